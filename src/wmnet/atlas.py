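"""The 90-region cerebrum parcellation node list (AAL-90).

The Automated Anatomical Labeling atlas' cerebrum portion has 90 regions,
45 per hemisphere, interleaved left/right in the standard ordering (odd
indices left, even indices right).  Only the node bookkeeping lives here —
spatial registration of the atlas to subject space is outside this
package's scope; label volumes arrive pre-aligned.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["aal90_nodes", "node_index", "write_node_list", "read_node_list"]

# 45 region abbreviations in standard AAL order (one per left/right pair).
_AAL45 = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING", "SOG",
    "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL",
    "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup", "MTG", "TPOmid",
    "ITG",
]


def aal90_nodes() -> pd.DataFrame:
    """Node table with columns ``index`` (1-based), ``abbrev``, ``hemisphere``.

    Abbreviations carry an ``.L``/``.R`` suffix (e.g. ``ACG.L``, ``IOG.R``);
    left precedes right within each region pair.
    """
    rows = []
    idx = 1
    for abbr in _AAL45:
        for hemi in ("L", "R"):
            rows.append({"index": idx, "abbrev": f"{abbr}.{hemi}", "hemisphere": hemi})
            idx += 1
    return pd.DataFrame(rows)


def node_index(nodes: pd.DataFrame, abbrev: str) -> int:
    """1-based index of a region abbreviation (e.g. ``'INS.L'``)."""
    hit = nodes.loc[nodes["abbrev"] == abbrev, "index"]
    if hit.empty:
        raise KeyError(f"unknown region abbreviation: {abbrev!r}")
    return int(hit.iloc[0])


def write_node_list(nodes: pd.DataFrame, path: str | Path) -> None:
    nodes.to_csv(path, sep="\t", index=False)


def read_node_list(path: str | Path) -> pd.DataFrame:
    nodes = pd.read_csv(path, sep="\t")
    expected = {"index", "abbrev", "hemisphere"}
    if not expected.issubset(nodes.columns):
        raise ValueError(f"node list must have columns {sorted(expected)}")
    return nodes
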