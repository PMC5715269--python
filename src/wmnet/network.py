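"""FA-weighted structural connectome construction from streamlines.

Two regions i and j are linked by an edge when at least one streamline
connects them; the edge is weighted by the mean FA of those streamlines
(mean over streamlines of each streamline's mean FA along its visited
voxels), which serves as the connectivity strength.  A streamline counts
for pair (i, j) when its two terminal points fall in the two ROIs
(endpoint semantics; a pass-through variant is available behind a flag).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import read_node_list, write_node_list
from .tensor import TensorField
from .tracking import Streamline

__all__ = [
    "LabelVolume",
    "Connectome",
    "assign_endpoints",
    "build_connectome",
    "read_connectome_matrix",
    "write_connectome_matrix",
]


@dataclasses.dataclass(frozen=True)
class LabelVolume:
    """3-D integer ROI labels (0 = background) plus the node table."""

    labels: np.ndarray
    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.ndim != 3:
            raise ValueError("label volume must be 3-D")
        present = set(np.unique(lab)) - {0}
        known = set(self.nodes["index"].astype(int))
        unknown = sorted(present - known)
        if unknown:
            raise ValueError(f"labels not in node list: {unknown}")
        object.__setattr__(self, "labels", lab)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def label_at(self, point: np.ndarray) -> int:
        """ROI id at a voxel-coordinate point; outside the volume is background."""
        v = np.floor(np.asarray(point, dtype=float)).astype(int)
        if np.any(v < 0) or np.any(v >= np.array(self.labels.shape)):
            return 0
        return int(self.labels[v[0], v[1], v[2]])


@dataclasses.dataclass(frozen=True)
class Connectome:
    """Symmetric FA-weight and streamline-count matrices with node table.

    ``weights[i, j] > 0`` exactly when ``counts[i, j] >= 1``; weights lie
    in [0, 1] (they are means of FA values); diagonals are zero.
    """

    weights: np.ndarray
    counts: np.ndarray
    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        c = np.asarray(self.counts)
        n = len(self.nodes)
        if w.shape != (n, n) or c.shape != (n, n):
            raise ValueError("matrix shape must match node list length")
        if np.max(np.abs(w - w.T)) > 1e-8:
            raise ValueError("weight matrix not symmetric (asymmetry > 1e-8)")
        if np.any(np.diag(w) != 0) or np.any(np.diag(c) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("FA edge weights must lie in [0, 1]")
        if np.any((w > 0) != (c > 0)):
            raise ValueError("weights and counts must share a support")
        object.__setattr__(self, "weights", 0.5 * (w + w.T))
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def assign_endpoints(
    streamline: Streamline, labels: LabelVolume, pass_through: bool = False
) -> tuple[int, int] | None:
    """ROI pair connected by a streamline, or None.

    Endpoint semantics (default): both terminal points must fall in
    distinct nonzero ROIs; returns the pair ordered (min, max).  With
    ``pass_through=True`` the first and last *visited* ROI along the path
    are used instead.
    """
    if len(streamline) < 2:
        raise ValueError("degenerate streamline (<2 points)")
    if pass_through:
        visited = [
            lab
            for lab in (labels.label_at(p) for p in streamline.points)
            if lab != 0
        ]
        if not visited:
            return None
        i, j = visited[0], visited[-1]
    else:
        start, end = streamline.endpoints
        i, j = labels.label_at(start), labels.label_at(end)
    if i == 0 or j == 0 or i == j:
        return None
    return (min(i, j), max(i, j))


def build_connectome(
    streamlines: list[Streamline],
    field: TensorField,
    labels: LabelVolume,
    pass_through: bool = False,
) -> Connectome:
    """Aggregate streamlines into count and mean-FA weight matrices.

    ``counts[i, j]`` is the number of streamlines assigned to (i, j);
    ``weights[i, j]`` is the mean over those streamlines of the mean FA
    along each streamline's visited voxels (0 where no streamline).
    """
    n = labels.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes to build a connectome")
    counts = np.zeros((n, n), dtype=int)
    fa_sums = np.zeros((n, n), dtype=float)
    for s in streamlines:
        pair = assign_endpoints(s, labels, pass_through=pass_through)
        if pair is None:
            continue
        i, j = pair[0] - 1, pair[1] - 1  # labels are 1-based
        vox = s.voxels
        mean_fa = float(np.mean(field.fa[vox[:, 0], vox[:, 1], vox[:, 2]]))
        counts[i, j] += 1
        counts[j, i] += 1
        fa_sums[i, j] += mean_fa
        fa_sums[j, i] += mean_fa
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(counts > 0, fa_sums / np.maximum(counts, 1), 0.0)
    return Connectome(np.clip(weights, 0.0, 1.0), counts, labels.nodes)


def write_connectome_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """One whitespace-delimited N x N matrix per file."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.8g")


def read_connectome_matrix(path: str | Path) -> np.ndarray:
    """Read an N x N delimited text matrix (whitespace or comma)."""
    try:
        mat = np.loadtxt(path, ndmin=2)
    except ValueError:
        mat = np.loadtxt(path, delimiter=",", ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"matrix in {path} is not square: {mat.shape}")
    return mat
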