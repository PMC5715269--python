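"""Deterministic FACT-style streamline tractography.

Fiber Assignment by Continuous Tracking (FACT) propagates a streamline
bidirectionally along the principal eigenvector of the local diffusion
tensor.  A path terminates when it would enter a voxel whose FA does not
exceed the FA threshold, when the turning angle between successive steps
exceeds the angle threshold, or when it leaves the volume.

Conventions used here (documented defaults, see docs/methods.md):

* half-voxel steps with nearest-neighbour tensor lookup;
* one seed at the centre of every voxel with FA above threshold;
* eigenvector sign chosen to maximise the dot product with the previous
  step direction (the principal axis is direction-ambiguous);
* turning angle measured between successive step vectors, termination on
  strictly greater than the threshold (a step at exactly 45 deg continues);
* streamlines with fewer than two points are discarded as degenerate.

Tracking is a pure function of the tensor field: no randomness.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .tensor import TensorField

__all__ = ["Streamline", "track_fact", "write_streamlines", "read_streamlines"]


@dataclasses.dataclass(frozen=True)
class Streamline:
    """Ordered polyline in voxel coordinates with per-point voxel indices."""

    points: np.ndarray  # (n, 3) float
    voxels: np.ndarray  # (n, 3) int, voxel containing each point

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=int))

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]

    def max_turning_angle_deg(self) -> float:
        """Largest angle between successive segments (0 for <3 points)."""
        segs = np.diff(self.points, axis=0)
        if segs.shape[0] < 2:
            return 0.0
        a, b = segs[:-1], segs[1:]
        cos = np.sum(a * b, axis=1) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        return float(np.degrees(np.arccos(np.clip(cos.min(), -1.0, 1.0))))


def _propagate(
    field: TensorField,
    start: np.ndarray,
    init_dir: np.ndarray,
    fa_threshold: float,
    cos_threshold: float,
    step: float,
    max_steps: int,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """One tracking branch from ``start``; returns points/voxels past the seed."""
    shape = np.array(field.shape)
    pts: list[np.ndarray] = []
    voxs: list[np.ndarray] = []
    p = start.astype(float)
    prev = init_dir / np.linalg.norm(init_dir)
    for _ in range(max_steps):
        v = np.floor(p).astype(int)
        e = field.principal_directions[v[0], v[1], v[2]].copy()
        d = float(np.dot(e, prev))
        if d < 0:
            e = -e
            d = -d
        # termination: turning angle strictly greater than threshold
        if d < cos_threshold - 1e-12:
            break
        p_next = p + step * e
        v_next = np.floor(p_next).astype(int)
        if np.any(v_next < 0) or np.any(v_next >= shape):
            break
        if field.fa[v_next[0], v_next[1], v_next[2]] <= fa_threshold:
            break
        pts.append(p_next)
        voxs.append(v_next)
        p = p_next
        prev = e
    return pts, voxs


def track_fact(
    field: TensorField,
    fa_threshold: float = 0.2,
    angle_threshold_deg: float = 45.0,
    step: float = 0.5,
    max_steps: int = 2000,
) -> list[Streamline]:
    """Whole-volume deterministic streamline tracking.

    Seeds are placed at the centre of every voxel with FA > ``fa_threshold``
    and propagated in both directions along the principal eigenvector.

    Returns streamlines ordered by seed voxel (C order); an empty seed set
    yields an empty list.
    """
    if not np.all(np.isfinite(field.tensors)):
        raise ValueError("tensor field contains non-finite values")
    cos_threshold = float(np.cos(np.radians(angle_threshold_deg)))
    seeds = np.argwhere(field.fa > fa_threshold)
    out: list[Streamline] = []
    for idx in seeds:
        center = idx + 0.5
        e1 = field.principal_directions[idx[0], idx[1], idx[2]]
        fwd_p, fwd_v = _propagate(
            field, center, e1, fa_threshold, cos_threshold, step, max_steps
        )
        bwd_p, bwd_v = _propagate(
            field, center, -e1, fa_threshold, cos_threshold, step, max_steps
        )
        pts = bwd_p[::-1] + [center.astype(float)] + fwd_p
        voxs = bwd_v[::-1] + [idx] + fwd_v
        if len(pts) < 2:
            continue  # degenerate
        out.append(Streamline(np.array(pts), np.array(voxs)))
    return out


def write_streamlines(streamlines: list[Streamline], path: str | Path) -> None:
    """Plain-text format: one ``x y z`` point per line, blank line between
    streamlines."""
    with open(path, "w") as fh:
        for k, s in enumerate(streamlines):
            if k:
                fh.write("\n")
            for p in s.points:
                fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")


def read_streamlines(path: str | Path) -> list[Streamline]:
    """Inverse of :func:`write_streamlines`; voxel indices recomputed by floor."""
    blocks: list[list[list[float]]] = [[]]
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if blocks[-1]:
                    blocks.append([])
                continue
            blocks[-1].append([float(t) for t in line.split()])
    out = []
    for blk in blocks:
        if not blk:
            continue
        pts = np.array(blk, dtype=float)
        out.append(Streamline(pts, np.floor(pts).astype(int)))
    return out
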