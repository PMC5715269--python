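"""Synthetic diffusion-weighted phantoms with known fiber geometry.

A phantom is a small 3-D grid of single-tensor voxels: axis-aligned tube
"bundles" of high, known FA embedded in an isotropic background, with ROI
labels stamped on the bundle end caps.  The diffusion-weighted signal is
synthesised per voxel from the ground-truth tensor via the Stejskal–Tanner
equation, optionally with additive Gaussian noise, so the whole
tractography-to-connectome chain can be validated against analytic truth.

Bundles are straight or single-bend tubes on a desk-scale grid (<= 32^3):
endpoints and the analytic within-bundle FA are known exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .tensor import (
    GradientTable,
    TensorField,
    axially_symmetric_tensor,
    fit_tensor_field,
    uniform_gradient_table,
)

__all__ = [
    "Bundle",
    "PhantomSpec",
    "DWIPhantom",
    "generate_phantom",
    "straight_bundle_spec",
    "bent_bundle_spec",
    "save_phantom",
    "load_phantom",
]

_AXES = {0: "x", 1: "y", 2: "z"}


@dataclasses.dataclass(frozen=True)
class Bundle:
    """An axis-aligned tube with one or two straight segments.

    ``segments`` is a sequence of (axis, signed_length) pairs; the
    centerline starts at ``start`` and walks each segment in turn.  Voxels
    within Chebyshev radius ``radius`` of the centerline (in the plane
    perpendicular to the segment) belong to the tube.  The first and last
    ``roi_depth`` centerline slices are labelled ``roi_start``/``roi_end``.
    """

    start: tuple[int, int, int]
    segments: tuple[tuple[int, int], ...]
    radius: int = 1
    fa: float = 0.8
    roi_start: int = 1
    roi_end: int = 2
    roi_depth: int = 2

    def centerline(self) -> tuple[np.ndarray, np.ndarray]:
        """(voxels (n,3) int, unit direction per voxel (n,3) float)."""
        pos = np.array(self.start, dtype=int)
        voxels = [pos.copy()]
        first_axis = self.segments[0][0]
        dirs = [_unit(first_axis, np.sign(self.segments[0][1]) or 1)]
        for axis, length in self.segments:
            sgn = int(np.sign(length)) or 1
            for _ in range(abs(int(length))):
                pos = pos + sgn * np.eye(3, dtype=int)[axis]
                voxels.append(pos.copy())
                dirs.append(_unit(axis, sgn))
        return np.array(voxels), np.array(dirs)


def _unit(axis: int, sgn: int) -> np.ndarray:
    e = np.zeros(3)
    e[axis] = float(sgn)
    return e


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic DWI phantom.

    Defaults mirror a clinical single-shell scheme (64 directions,
    b = 1000 s/mm^2) on a small grid.  Bundle FA must exceed the standard
    0.2 tracking threshold; the isotropic background has FA 0 (< 0.2 with
    noise, by a wide margin at the default noise level).
    """

    shape: tuple[int, int, int] = (20, 7, 7)
    bundles: tuple[Bundle, ...] = ()
    background_diffusivity: float = 0.7e-3  # mm^2/s, isotropic
    bundle_diffusivity: float = 0.7e-3  # mean diffusivity inside bundles
    b_value: float = 1000.0
    n_gradients: int = 64
    noise_sd: float = 0.0
    s0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gradients < 6:
            raise ValueError("n_gradients must be >= 6 (tensor under-determined)")
        if any(s < 1 or s > 32 for s in self.shape):
            raise ValueError("phantom grid dimensions must lie in [1, 32]")
        for b in self.bundles:
            if not 0.2 < b.fa <= 1.0:
                raise ValueError("bundle FA target must lie in (0.2, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclasses.dataclass(frozen=True)
class DWIPhantom:
    """Synthetic DWI dataset: signal, gradient scheme, truth, ROI labels."""

    signals: np.ndarray  # (X, Y, Z, n_measurements)
    gradients: GradientTable
    truth: TensorField  # ground-truth tensors
    labels: np.ndarray  # (X, Y, Z) int, 0 = background
    spec: PhantomSpec

    def fit(self) -> TensorField:
        """Tensor field estimated from the noisy signals."""
        return fit_tensor_field(self.signals, self.gradients)


def generate_phantom(spec: PhantomSpec) -> DWIPhantom:
    """Build the ground-truth tensor field, synthesise signal, stamp ROIs.

    Signal: S = S0 * exp(-b g'Dg) + eps, eps ~ N(0, noise_sd), seeded.
    """
    nx, ny, nz = spec.shape
    iso = np.eye(3) * spec.background_diffusivity
    tensors = np.broadcast_to(iso, (nx, ny, nz, 3, 3)).copy()
    labels = np.zeros(spec.shape, dtype=int)

    for bundle in spec.bundles:
        voxels, dirs = bundle.centerline()
        n_center = voxels.shape[0]
        for k in range(n_center):
            v, d = voxels[k], dirs[k]
            tens = axially_symmetric_tensor(bundle.fa, spec.bundle_diffusivity, d)
            axis = int(np.argmax(np.abs(d)))
            label = 0
            if k < bundle.roi_depth:
                label = bundle.roi_start
            elif k >= n_center - bundle.roi_depth:
                label = bundle.roi_end
            for off in _cross_section_offsets(axis, bundle.radius):
                w = v + off
                if np.any(w < 0) or np.any(w >= spec.shape):
                    raise ValueError(
                        f"bundle leaves the grid at voxel {tuple(w)}"
                    )
                tensors[w[0], w[1], w[2]] = tens
                if label:
                    labels[w[0], w[1], w[2]] = label

    truth = TensorField(tensors)
    gtab = uniform_gradient_table(spec.n_gradients, spec.b_value)
    g = gtab.directions
    quad = np.einsum("ni,xyzij,nj->xyzn", g, tensors, g)
    clean = spec.s0 * np.exp(-gtab.b_values * quad)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, clean.shape) if spec.noise_sd > 0 else 0.0
    return DWIPhantom(clean + noise, gtab, truth, labels, spec)


def _cross_section_offsets(axis: int, radius: int) -> list[np.ndarray]:
    """Integer offsets spanning the tube cross-section (Chebyshev disk)."""
    other = [a for a in range(3) if a != axis]
    offsets = []
    for u in range(-radius, radius + 1):
        for w in range(-radius, radius + 1):
            off = np.zeros(3, dtype=int)
            off[other[0]] = u
            off[other[1]] = w
            offsets.append(off)
    return offsets


def straight_bundle_spec(
    length: int = 16,
    fa: float = 0.8,
    noise_sd: float = 0.0,
    seed: int = 0,
    radius: int = 1,
    n_gradients: int = 64,
) -> PhantomSpec:
    """A single straight tube along x with ROI caps at both ends."""
    ny = nz = 2 * radius + 3
    c = ny // 2
    bundle = Bundle(
        start=(2, c, c), segments=((0, length),), radius=radius, fa=fa
    )
    return PhantomSpec(
        shape=(length + 5, ny, nz),
        bundles=(bundle,),
        noise_sd=noise_sd,
        seed=seed,
        n_gradients=n_gradients,
    )


def bent_bundle_spec(
    arm: int = 10,
    fa: float = 0.8,
    noise_sd: float = 0.0,
    seed: int = 0,
    radius: int = 1,
    n_gradients: int = 64,
) -> PhantomSpec:
    """An L-shaped tube: along +x then a 90-degree bend to +y."""
    nz = 2 * radius + 3
    c = nz // 2
    bundle = Bundle(
        start=(2, 2, c),
        segments=((0, arm), (1, arm)),
        radius=radius,
        fa=fa,
    )
    return PhantomSpec(
        shape=(arm + 5, arm + 5, nz),
        bundles=(bundle,),
        noise_sd=noise_sd,
        seed=seed,
        n_gradients=n_gradients,
    )


def save_phantom(phantom: DWIPhantom, outdir: str | Path, fmt: str = "text") -> None:
    """Write signals, gradient table and labels.

    ``fmt='text'``: delimited-text fallback (flattened signal array with a
    JSON shape sidecar).  ``fmt='nifti'``: NIfTI via nibabel if installed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phantom.gradients.to_text(outdir / "gradients.txt")
    if fmt == "text":
        shape = phantom.signals.shape
        (outdir / "shape.json").write_text(json.dumps({"signals": list(shape)}))
        np.savetxt(outdir / "signals.txt", phantom.signals.reshape(-1, shape[3]))
        np.savetxt(outdir / "labels.txt", phantom.labels.reshape(-1, 1), fmt="%d")
    elif fmt == "nifti":
        import nibabel as nib

        aff = np.eye(4)
        nib.save(nib.Nifti1Image(phantom.signals, aff), outdir / "signals.nii.gz")
        nib.save(
            nib.Nifti1Image(phantom.labels.astype(np.int16), aff),
            outdir / "labels.nii.gz",
        )
    else:
        raise ValueError(f"unknown phantom format: {fmt!r}")


def load_phantom(indir: str | Path) -> tuple[np.ndarray, GradientTable, np.ndarray]:
    """Read back a text-format phantom: (signals, gradients, labels)."""
    indir = Path(indir)
    gtab = GradientTable.from_text(indir / "gradients.txt")
    shape = tuple(json.loads((indir / "shape.json").read_text())["signals"])
    signals = np.loadtxt(indir / "signals.txt").reshape(shape)
    labels = np.loadtxt(indir / "labels.txt", dtype=int).reshape(shape[:3])
    return signals, gtab, labels
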