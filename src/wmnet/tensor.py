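"""Diffusion-tensor estimation and fractional anisotropy.

The single-tensor model of diffusion MRI relates the measured signal in a
voxel to an apparent diffusion tensor ``D`` (a symmetric positive 3x3 matrix,
mm^2/s) through the Stejskal–Tanner equation

    S(g, b) = S0 * exp(-b * g' D g)

where ``g`` is a unit gradient direction and ``b`` the diffusion weighting
(s/mm^2).  Taking logs makes the model linear in the six unique tensor
elements plus ``log S0``, so the tensor is recovered by linear least squares
from seven or more measurements (at least six non-collinear weighted
directions and one b=0 image).

Fractional anisotropy (FA) summarises the directional dependence of the
fitted tensor on a [0, 1] scale from its eigenvalues.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "GradientTable",
    "DiffusionTensor",
    "TensorField",
    "fractional_anisotropy",
    "fit_tensor",
    "fit_tensor_field",
    "axially_symmetric_tensor",
    "synthesize_signal",
]


@dataclasses.dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: unit directions and b-values.

    Parameters
    ----------
    directions
        (n, 3) array; rows with nonzero b must be unit norm (within 1e-6).
    b_values
        (n,) array of b-values in s/mm^2. At least one entry must be 0 and
        at least six entries nonzero.
    """

    directions: np.ndarray
    b_values: np.ndarray

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions, dtype=float)
        bvals = np.asarray(self.b_values, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        if bvals.shape != (dirs.shape[0],):
            raise ValueError("b_values length must match directions")
        if not np.any(bvals == 0):
            raise ValueError("gradient table needs at least one b=0 entry")
        dw = bvals > 0
        if dw.sum() < 6:
            raise ValueError(
                "tensor fit is under-determined: need >=6 diffusion-weighted "
                f"directions, got {int(dw.sum())}"
            )
        norms = np.linalg.norm(dirs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit norm")
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "b_values", bvals)

    def __len__(self) -> int:
        return self.directions.shape[0]

    def design_matrix(self) -> np.ndarray:
        """Design matrix for the log-linear fit.

        Columns correspond to [log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]
        so that ``X @ beta = log S``.
        """
        g = self.directions
        b = self.b_values
        gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
        return np.column_stack(
            [
                np.ones_like(b),
                -b * gx * gx,
                -b * gy * gy,
                -b * gz * gz,
                -2.0 * b * gx * gy,
                -2.0 * b * gx * gz,
                -2.0 * b * gy * gz,
            ]
        )

    def to_text(self, path: str | Path) -> None:
        """Write as 4-column text ``gx gy gz b`` (one row per measurement)."""
        out = np.column_stack([self.directions, self.b_values])
        np.savetxt(path, out, fmt="%.10g", header="gx gy gz b")

    @classmethod
    def from_text(cls, path: str | Path) -> "GradientTable":
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] != 4:
            raise ValueError("gradient table text must have 4 columns: gx gy gz b")
        return cls(arr[:, :3], arr[:, 3])


def uniform_gradient_table(n_gradients: int = 64, b_value: float = 1000.0) -> GradientTable:
    """Quasi-uniform gradient scheme: Fibonacci-sphere directions plus one b=0.

    The default mirrors a common clinical scheme of 64 non-collinear
    directions at b = 1000 s/mm^2.
    """
    if n_gradients < 6:
        raise ValueError("n_gradients must be >= 6 (tensor under-determined)")
    i = np.arange(n_gradients, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n_gradients
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    dirs = np.vstack([[0.0, 0.0, 0.0], dirs])
    bvals = np.concatenate([[0.0], np.full(n_gradients, float(b_value))])
    return GradientTable(dirs, bvals)


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray | float:
    """FA from tensor eigenvalues, clamped to [0, 1].

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, with FA := 0
    for an all-zero eigenvalue triple.  Accepts a length-3 vector or an
    (..., 3) stack; scale-invariant by construction.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    scalar = lam.ndim == 1
    lam = np.atleast_2d(lam)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den == 0, 0.0, fa)
    fa = np.clip(fa, 0.0, 1.0)
    return float(fa[0]) if scalar else fa


@dataclasses.dataclass(frozen=True)
class DiffusionTensor:
    """A fitted symmetric diffusion tensor with its eigensystem."""

    tensor: np.ndarray  # (3, 3) symmetric, mm^2/s
    s0: float

    def __post_init__(self) -> None:
        d = np.asarray(self.tensor, dtype=float)
        d = 0.5 * (d + d.T)  # enforce exact symmetry
        object.__setattr__(self, "tensor", d)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending (lambda1 >= lambda2 >= lambda3)."""
        return np.linalg.eigvalsh(self.tensor)[::-1]

    @property
    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues descending, eigenvectors as columns e1, e2, e3)."""
        w, v = np.linalg.eigh(self.tensor)
        return w[::-1], v[:, ::-1]

    @property
    def fa(self) -> float:
        return float(fractional_anisotropy(self.eigenvalues))

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigensystem[1][:, 0]


def fit_tensor(signals: np.ndarray, gradients: GradientTable) -> DiffusionTensor:
    """Linear least-squares tensor fit for one voxel.

    Minimises ``|| log(S) - X beta ||^2`` with the log-linear design of
    :meth:`GradientTable.design_matrix`.

    Raises
    ------
    ValueError
        If any signal is non-positive (log undefined) or fewer than seven
        measurements are provided.
    numpy.linalg.LinAlgError
        If the design matrix is rank-deficient (collinear gradients).
    """
    s = np.asarray(signals, dtype=float)
    if s.shape != (len(gradients),):
        raise ValueError("signals length must match gradient table")
    if len(gradients) < 7:
        raise ValueError("need >=7 measurements (6 weighted + 1 b=0)")
    if np.any(s <= 0):
        raise ValueError("non-positive signal: log-linear fit undefined")
    x = gradients.design_matrix()
    if np.linalg.matrix_rank(x) < 7:
        raise np.linalg.LinAlgError("rank-deficient gradient design")
    beta, *_ = np.linalg.lstsq(x, np.log(s), rcond=None)
    d = _tensor_from_beta(beta)
    return DiffusionTensor(tensor=d, s0=float(np.exp(beta[0])))


def _tensor_from_beta(beta: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = beta[1:7]
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def synthesize_signal(
    tensor: np.ndarray, gradients: GradientTable, s0: float = 1.0
) -> np.ndarray:
    """Noise-free signal for a tensor under a gradient scheme (one voxel)."""
    d = np.asarray(tensor, dtype=float)
    g = gradients.directions
    quad = np.einsum("ni,ij,nj->n", g, d, g)
    return s0 * np.exp(-gradients.b_values * quad)


def axially_symmetric_tensor(
    fa: float, mean_diffusivity: float, direction: np.ndarray
) -> np.ndarray:
    """Cylindrically symmetric tensor with prescribed FA and mean diffusivity.

    Eigenvalues are ``m(1+2d), m(1-d), m(1-d)`` with ``d`` solving
    FA = 3d / sqrt(3 + 6 d^2); the principal axis is ``direction``.
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError("fa must lie in [0, 1)")
    m = float(mean_diffusivity)
    delta = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa * fa))
    lam = np.array([m * (1 + 2 * delta), m * (1 - delta), m * (1 - delta)])
    e1 = np.asarray(direction, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    # complete an orthonormal frame around e1
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, e1)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    basis = np.column_stack([e1, e2, e3])
    return basis @ np.diag(lam) @ basis.T


class TensorField:
    """Per-voxel diffusion tensors over a 3-D grid, with FA map.

    Parameters
    ----------
    tensors
        (X, Y, Z, 3, 3) array of symmetric tensors.
    voxel_size
        Edge lengths in mm (isotropic default 1.0); informational only —
        tracking operates in voxel coordinates.
    """

    def __init__(self, tensors: np.ndarray, voxel_size: float = 1.0):
        t = np.asarray(tensors, dtype=float)
        if t.ndim != 5 or t.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (X, Y, Z, 3, 3)")
        self.tensors = 0.5 * (t + np.swapaxes(t, 3, 4))
        self.voxel_size = float(voxel_size)
        w, v = np.linalg.eigh(self.tensors)
        # eigh returns ascending order; flip to descending
        self.eigenvalues = w[..., ::-1]
        self.principal_directions = v[..., :, ::-1][..., :, 0]
        self.fa = fractional_anisotropy(self.eigenvalues)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]


def fit_tensor_field(
    signals: np.ndarray,
    gradients: GradientTable,
    voxel_size: float = 1.0,
    signal_floor: float | None = 1e-6,
) -> TensorField:
    """Vectorised voxel-by-voxel linear least-squares tensor fit.

    ``signals`` has shape (X, Y, Z, n_measurements).  Noise can push a
    measured signal to or below zero where the true signal is small;
    such values are clipped to ``signal_floor`` before the log transform
    (set ``signal_floor=None`` to fail instead, as the single-voxel
    :func:`fit_tensor` does).
    """
    s = np.asarray(signals, dtype=float)
    if s.ndim != 4 or s.shape[3] != len(gradients):
        raise ValueError("signals must have shape (X, Y, Z, n_measurements)")
    if signal_floor is None:
        if np.any(s <= 0):
            raise ValueError("non-positive signal: log-linear fit undefined")
    else:
        s = np.maximum(s, signal_floor)
    x = gradients.design_matrix()
    if np.linalg.matrix_rank(x) < 7:
        raise np.linalg.LinAlgError("rank-deficient gradient design")
    logs = np.log(s).reshape(-1, len(gradients)).T  # (n, n_voxels)
    beta, *_ = np.linalg.lstsq(x, logs, rcond=None)  # (7, n_voxels)
    n_vox = beta.shape[1]
    tensors = np.empty((n_vox, 3, 3))
    tensors[:, 0, 0] = beta[1]
    tensors[:, 1, 1] = beta[2]
    tensors[:, 2, 2] = beta[3]
    tensors[:, 0, 1] = tensors[:, 1, 0] = beta[4]
    tensors[:, 0, 2] = tensors[:, 2, 0] = beta[5]
    tensors[:, 1, 2] = tensors[:, 2, 1] = beta[6]
    return TensorField(tensors.reshape(*s.shape[:3], 3, 3), voxel_size=voxel_size)
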