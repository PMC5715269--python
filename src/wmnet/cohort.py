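"""Synthetic cohorts: covariate tables and group-structured connectomes.

This module emulates the study conditions of a two-group observational
design: healthy adults with insomnia symptoms (IS, insomnia score >= 1 on
the three HAMD-17 sleep items) versus without (NIS, score 0), with
covariate distributions matching the published group summaries (n = 30 vs
62; age ~38 y; HAMD/HAMA totals decomposed as adjusted score + sleep
component so that adjusted <= total holds by construction).

Connectomes are drawn from a distance-dependent random geometric model on
bilateral node positions with spatially coherent modules and a homotopic
(mirror-pair) bonus; per-subject FA edge weights are Beta-distributed
around the model affinity.  Group differences are planted by rescaling
within-module weights (raises local efficiency), between-module weights
(lowers global efficiency when negative), node-incident weights (nodal
effects), or by coupling node-incident weights to the insomnia score.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .atlas import aal90_nodes, node_index
from .network import Connectome, write_connectome_matrix

__all__ = [
    "GroupMoments",
    "CohortSpec",
    "NodalEffect",
    "InsomniaCoupling",
    "EffectSpec",
    "generate_cohort",
    "generate_connectomes",
    "write_cohort",
    "read_cohort",
    "save_connectomes",
    "IS_DEFAULTS",
    "NIS_DEFAULTS",
]

SUBJECT_COLUMNS = (
    "id", "group", "age", "gender", "education",
    "hamd", "hamd_adj", "hama", "hama_adj", "insomnia",
)


@dataclasses.dataclass(frozen=True)
class GroupMoments:
    """Per-group covariate moments (mean, SD) and the female fraction.

    ``hama_sleep`` is the sleep-related HAMA component (total minus
    adjusted); its mean is pinned by the published totals, its SD is a
    modelling choice.
    """

    age: tuple[float, float]
    education: tuple[float, float]
    hamd_adj: tuple[float, float]
    hama_adj: tuple[float, float]
    insomnia: tuple[float, float]
    hama_sleep: tuple[float, float]
    female_fraction: float

    def __post_init__(self) -> None:
        for name in ("age", "education", "hamd_adj", "hama_adj", "insomnia", "hama_sleep"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"SD of {name!r} must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")


IS_DEFAULTS = GroupMoments(
    age=(38.00, 11.85),
    education=(14.07, 3.34),
    hamd_adj=(1.23, 1.31),
    hama_adj=(1.97, 2.00),
    insomnia=(1.70, 0.92),
    hama_sleep=(1.23, 0.90),
    female_fraction=15 / 30,
)

NIS_DEFAULTS = GroupMoments(
    age=(37.47, 11.95),
    education=(15.42, 2.95),
    hamd_adj=(0.19, 0.51),
    hama_adj=(0.32, 0.79),
    insomnia=(0.00, 0.00),
    hama_sleep=(0.00, 0.00),
    female_fraction=36 / 62,
)


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes, per-group covariate moments and the RNG seed."""

    n_is: int = 30
    n_nis: int = 62
    is_moments: GroupMoments = IS_DEFAULTS
    nis_moments: GroupMoments = NIS_DEFAULTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_is < 2:
            raise ValueError("n_is must be >= 2")
        if self.n_nis < 2:
            raise ValueError("n_nis must be >= 2")


def _discrete_moment_probs(
    mean: float, sd: float, support: np.ndarray
) -> np.ndarray:
    """Probabilities of a truncated discrete Gaussian on ``support`` whose
    location/scale are moment-matched to (mean, sd) by Nelder–Mead."""
    support = np.asarray(support, dtype=float)
    if sd == 0:
        probs = np.zeros(support.size)
        probs[int(np.argmin(np.abs(support - mean)))] = 1.0
        return probs

    def probs_for(mu: float, log_sigma: float) -> np.ndarray:
        sigma = np.exp(log_sigma)
        w = np.exp(-0.5 * ((support - mu) / sigma) ** 2)
        if w.sum() == 0:  # degenerate scale: collapse to nearest support point
            w = np.zeros(support.size)
            w[int(np.argmin(np.abs(support - mu)))] = 1.0
        return w / w.sum()

    def loss(params: np.ndarray) -> float:
        p = probs_for(params[0], params[1])
        m = float(np.sum(p * support))
        v = float(np.sum(p * support**2) - m * m)
        return (m - mean) ** 2 + (np.sqrt(max(v, 0.0)) - sd) ** 2

    res = minimize(loss, x0=np.array([mean, np.log(max(sd, 0.1))]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    return probs_for(res.x[0], res.x[1])


def _draw_discrete(
    rng: np.random.Generator, n: int, mean: float, sd: float, support: np.ndarray
) -> np.ndarray:
    probs = _discrete_moment_probs(mean, sd, support)
    return rng.choice(support, size=n, p=probs).astype(int)


def _group_records(
    rng: np.random.Generator,
    n: int,
    group: str,
    moments: GroupMoments,
) -> pd.DataFrame:
    age = rng.normal(moments.age[0], moments.age[1], n)
    education = np.clip(rng.normal(moments.education[0], moments.education[1], n), 0, None)
    female = rng.random(n) < moments.female_fraction
    if group == "IS":
        # insomnia score: sum of 3 HAMD-17 sleep items, >= 1 defines IS
        insomnia = _draw_discrete(rng, n, *moments.insomnia, np.arange(1, 7))
    else:
        insomnia = np.zeros(n, dtype=int)
    hamd_adj = _draw_discrete(rng, n, *moments.hamd_adj, np.arange(0, 21))
    hama_adj = _draw_discrete(rng, n, *moments.hama_adj, np.arange(0, 21))
    hama_sleep = _draw_discrete(rng, n, *moments.hama_sleep, np.arange(0, 7))
    return pd.DataFrame(
        {
            "id": [f"sub-{group}-{k + 1:03d}" for k in range(n)],
            "group": group,
            "age": np.round(age, 2),
            "gender": np.where(female, "F", "M"),
            "education": np.round(education, 2),
            "hamd": hamd_adj + insomnia,  # total = adjusted + sleep items
            "hamd_adj": hamd_adj,
            "hama": hama_adj + hama_sleep,
            "hama_adj": hama_adj,
            "insomnia": insomnia,
        }
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Subject table for a two-group cohort; deterministic given the spec.

    IS insomnia scores are drawn from {1..6} with moments matched to the
    spec; NIS scores are exactly 0.  HAMD/HAMA totals are built as
    adjusted score + sleep component, so adjusted <= total always.
    """
    rng = np.random.default_rng(spec.seed)
    is_tab = _group_records(rng, spec.n_is, "IS", spec.is_moments)
    nis_tab = _group_records(rng, spec.n_nis, "NIS", spec.nis_moments)
    return pd.concat([is_tab, nis_tab], ignore_index=True)[list(SUBJECT_COLUMNS)]


# ---------------------------------------------------------------------------
# connectome generation


@dataclasses.dataclass(frozen=True)
class NodalEffect:
    """Planted group difference at one node: scale its incident weights
    (IS subjects) by 1 + direction * magnitude."""

    node: int  # 1-based index
    metric: str  # 'degree' | 'efficiency' | 'betweenness' (informational)
    direction: int
    magnitude: float

    def __post_init__(self) -> None:
        if self.metric not in ("degree", "efficiency", "betweenness"):
            raise ValueError(f"unknown nodal metric {self.metric!r}")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")


@dataclasses.dataclass(frozen=True)
class InsomniaCoupling:
    """Slope linking a node's incident weights to the insomnia score."""

    node: int
    metric: str
    slope: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """Planted group-level and nodal effects for the connectome generator.

    ``eglo_shift``/``eloc_shift`` are signed multiplicative shifts applied
    in the IS group to between-module / within-module edge weights; a
    negative ``eglo_shift`` removes long-range shortcuts from the retained
    edge set (global efficiency falls), a positive ``eloc_shift``
    concentrates retained edges inside modules (local efficiency rises).
    """

    eglo_shift: float = 0.0
    eloc_shift: float = 0.0
    nodal: tuple[NodalEffect, ...] = ()
    coupling: tuple[InsomniaCoupling, ...] = ()

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls()

    @classmethod
    def insomnia_default(cls) -> "EffectSpec":
        """The disruption pattern this generator targets by default:
        higher local efficiency with lower global efficiency in the IS
        group, plus nodal alterations in occipital, fronto-limbic and
        default-mode regions and insomnia-score couplings in salience
        (insula) and sensorimotor regions."""
        nodes = aal90_nodes()

        def ix(abbr: str) -> int:
            return node_index(nodes, abbr)

        return cls(
            eglo_shift=-0.18,
            eloc_shift=0.18,
            nodal=(
                NodalEffect(ix("IOG.R"), "betweenness", +1, 0.25),
                NodalEffect(ix("TPOsup.R"), "betweenness", +1, 0.25),
                NodalEffect(ix("ACG.L"), "efficiency", +1, 0.25),
                NodalEffect(ix("SFGmed.L"), "efficiency", +1, 0.25),
                NodalEffect(ix("ORBmid.L"), "efficiency", -1, 0.25),
            ),
            coupling=(
                InsomniaCoupling(ix("INS.L"), "efficiency", -0.06),
                InsomniaCoupling(ix("INS.R"), "degree", +0.06),
                InsomniaCoupling(ix("PoCG.R"), "betweenness", -0.06),
            ),
        )


def _base_layout(
    rng: np.random.Generator, n_nodes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bilateral node positions and module labels (mirror symmetric)."""
    n_pairs = n_nodes // 2
    odd = n_nodes % 2
    # left-hemisphere positions in a unit slab, x in [-1, -0.05]
    u = rng.random((n_pairs, 3))
    left = np.column_stack([-(0.05 + 0.95 * u[:, 0]), u[:, 1], u[:, 2]])
    right = left * np.array([-1.0, 1.0, 1.0])
    pos = np.empty((n_nodes, 3))
    pos[0 : 2 * n_pairs : 2] = left
    pos[1 : 2 * n_pairs : 2] = right
    if odd:
        pos[-1] = np.array([0.0, rng.random(), rng.random()])
    # spatially coherent modules: nearest of M centroids, mirrored
    n_modules = max(2, n_pairs // 8)
    centroids = left[rng.choice(n_pairs, size=n_modules, replace=False)]
    d2 = ((left[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    mod_left = np.argmin(d2, axis=1)
    modules = np.empty(n_nodes, dtype=int)
    modules[0 : 2 * n_pairs : 2] = mod_left
    modules[1 : 2 * n_pairs : 2] = mod_left  # mirror pair shares a module
    if odd:
        modules[-1] = 0
    return pos, modules


def _affinity(
    pos: np.ndarray, modules: np.ndarray, length_scale: float = 0.5,
    module_bonus: float = 0.8, homotopic_bonus: float = 1.5,
) -> np.ndarray:
    """Edge affinity in [0, 1]: distance decay x community x homotopy."""
    n = pos.shape[0]
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    a = np.exp(-d / length_scale)
    same = modules[:, None] == modules[None, :]
    a *= 1.0 + module_bonus * same
    n_pairs = n // 2
    pair_i = np.arange(0, 2 * n_pairs, 2)
    a[pair_i, pair_i + 1] *= 1.0 + homotopic_bonus
    a[pair_i + 1, pair_i] *= 1.0 + homotopic_bonus
    np.fill_diagonal(a, 0.0)
    lo, hi = a[a > 0].min(), a.max()
    a = np.where(a > 0, (a - lo) / (hi - lo), 0.0)
    return a


def _effect_factor(
    n_nodes: int,
    modules: np.ndarray,
    effects: EffectSpec,
    is_subject_is: bool,
    insomnia_score: float,
) -> np.ndarray:
    f = np.ones((n_nodes, n_nodes))
    same = modules[:, None] == modules[None, :]
    if is_subject_is:
        f[same] *= 1.0 + effects.eloc_shift
        f[~same] *= 1.0 + effects.eglo_shift
        for eff in effects.nodal:
            if not 1 <= eff.node <= n_nodes:
                raise ValueError(
                    f"nodal effect index {eff.node} out of range [1, {n_nodes}]"
                )
            k = eff.node - 1
            scale = 1.0 + eff.direction * eff.magnitude
            f[k, :] *= scale
            f[:, k] *= scale
    for cpl in effects.coupling:
        if not 1 <= cpl.node <= n_nodes:
            raise ValueError(
                f"coupling node index {cpl.node} out of range [1, {n_nodes}]"
            )
        k = cpl.node - 1
        scale = max(1.0 + cpl.slope * insomnia_score, 0.0)
        f[k, :] *= scale
        f[:, k] *= scale
    np.fill_diagonal(f, 1.0)
    return f


def generate_connectomes(
    subjects: pd.DataFrame,
    n_nodes: int = 90,
    effects: EffectSpec | None = None,
    seed: int = 0,
    nodes: pd.DataFrame | None = None,
    weight_concentration: float = 40.0,
) -> dict[str, Connectome]:
    """One FA-weighted connectome per subject, keyed by subject id.

    Each matrix is symmetric with zero diagonal and weights in [0, 1];
    thresholded at sparsity 0.10 its largest connected component covers at
    least 90% of nodes (a property of the distance + community + homotopy
    affinity model, checked in the test suite).  Planted effects shift
    group-mean metric AUCs in the specified directions.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    effects = effects if effects is not None else EffectSpec.null()
    if nodes is None:
        if n_nodes == 90:
            nodes = aal90_nodes()
        else:
            half = ["L", "R"] * (n_nodes // 2) + ["M"] * (n_nodes % 2)
            nodes = pd.DataFrame(
                {
                    "index": np.arange(1, n_nodes + 1),
                    "abbrev": [f"N{k + 1:02d}.{h}" for k, h in enumerate(half)],
                    "hemisphere": half,
                }
            )
    rng = np.random.default_rng(seed)
    pos, modules = _base_layout(rng, n_nodes)
    affinity = _affinity(pos, modules)
    mu = 0.15 + 0.60 * affinity  # Beta mean per edge, FA-like range
    kappa = float(weight_concentration)
    iu, ju = np.triu_indices(n_nodes, 1)
    alpha = mu[iu, ju] * kappa
    beta = (1.0 - mu[iu, ju]) * kappa
    out: dict[str, Connectome] = {}
    for _, row in subjects.iterrows():
        w_upper = rng.beta(alpha, beta)
        w = np.zeros((n_nodes, n_nodes))
        w[iu, ju] = w_upper
        w += w.T
        f = _effect_factor(
            n_nodes, modules, effects, row["group"] == "IS", float(row["insomnia"])
        )
        w = np.clip(w * f, 0.0, 1.0)
        np.fill_diagonal(w, 0.0)
        counts = (w > 0).astype(int)  # placeholder fiber counts (>=1 per edge)
        out[str(row["id"])] = Connectome(w, counts, nodes)
    return out


# ---------------------------------------------------------------------------
# I/O


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = set(SUBJECT_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return tab


def save_connectomes(connectomes: dict[str, Connectome], outdir: str | Path) -> None:
    """Write one ``<id>.mat.txt`` weight matrix per subject."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, conn in connectomes.items():
        write_connectome_matrix(conn.weights, outdir / f"{sid}.mat.txt")
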