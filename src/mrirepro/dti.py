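"""Single diffusion-tensor estimation and derived scalar maps.

A per-voxel symmetric tensor D (mm^2/s) is fitted to the log-signal model

    ln S_k = ln S0 - b_k * g_k^T D g_k

by linear least squares with iteratively-reweighted robust (Huber)
refinement, from which fractional anisotropy and mean diffusivity are
computed.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import GridMismatchError

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionScheme",
    "DWISeries",
    "TensorField",
    "design_matrix",
    "fit_tensor_field",
    "compute_fa",
    "compute_md",
]

#: tensor coefficient order used throughout: Dxx, Dxy, Dxz, Dyy, Dyz, Dzz
TENSOR_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

_UNIT_TOL = 1e-6


@dataclasses.dataclass
class DiffusionScheme:
    """A diffusion acquisition scheme: b-values plus unit gradient directions.

    Parameters
    ----------
    bvals : ndarray, shape (N,)
        Diffusion weightings in s/mm^2 (>= 0).
    bvecs : ndarray, shape (N, 3)
        Gradient directions; must be unit-norm for b > 0.  Directions at
        b = 0 are ignored and may be zero.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=np.float64).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} does not match "
                f"{self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be nonnegative")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("gradient directions must be unit-norm for b > 0")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    def is_well_posed(self) -> bool:
        """At least one b=0 and >= 6 unique directions at b > 0."""
        if self.n_b0 < 1:
            return False
        dirs = self.bvecs[self.bvals > 0]
        if dirs.shape[0] < 6:
            return False
        # antipodal directions sample the same tensor projection
        canon = np.where(dirs[:, :1] >= 0, dirs, -dirs)
        uniq = np.unique(np.round(canon, 6), axis=0)
        return uniq.shape[0] >= 6


@dataclasses.dataclass
class DWISeries:
    """A 4D diffusion-weighted signal stack paired with its scheme."""

    data: np.ndarray
    scheme: DiffusionScheme
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("DWISeries requires 4D data (x, y, z, measurement)")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"series has {self.data.shape[3]} volumes but scheme has "
                f"{len(self.scheme)} entries"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclasses.dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor plus derived eigensystem.

    Attributes
    ----------
    coefficients : ndarray, shape (..., 6)
        Unique tensor entries in :data:`TENSOR_ORDER`, mm^2/s.
    s0 : ndarray
        Fitted baseline signal per voxel.
    eigenvalues : ndarray, shape (..., 3)
        Sorted descending; negative values clamped to zero.
    n_clamped : int
        Number of eigenvalues clamped to zero across the volume.
    """

    coefficients: np.ndarray
    s0: np.ndarray
    eigenvalues: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_clamped: int = 0

    @property
    def shape(self):
        return self.coefficients.shape[:-1]

    def as_matrices(self) -> np.ndarray:
        """Expand the 6 unique coefficients to full (..., 3, 3) matrices."""
        c = self.coefficients
        m = np.empty(c.shape[:-1] + (3, 3), dtype=np.float64)
        m[..., 0, 0] = c[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 2]
        m[..., 1, 1] = c[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 4]
        m[..., 2, 2] = c[..., 5]
        return m


def design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """Build the (N, 7) log-linear design matrix.

    Columns: [1, -b gx^2, -2b gx gy, -2b gx gz, -b gy^2, -2b gy gz, -b gz^2],
    matching parameter vector [ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz].
    """
    b = scheme.bvals
    g = scheme.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -b * gy * gy,
            -2.0 * b * gy * gz,
            -b * gz * gz,
        ]
    )
    return X


def _batched_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve per-voxel weighted least squares.

    X: (N, P); y: (V, N); w: (V, N) nonnegative weights.
    Returns beta: (V, P).
    """
    A = np.einsum("ni,vn,nj->vij", X, w, X, optimize=True)
    rhs = np.einsum("ni,vn->vi", X, w * y, optimize=True)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def fit_tensor_field(
    dwi: DWISeries,
    mask: np.ndarray | None = None,
    *,
    robust: bool = True,
    huber_c: float = 1.345,
    max_iter: int = 50,
    param_tol: float = 1e-10,
) -> TensorField:
    """Fit a single diffusion tensor per voxel.

    The log-linear system is first solved by ordinary least squares, then
    (when ``robust``) refined by IRLS with Huber weights.  The Huber
    threshold is ``huber_c`` times the median absolute deviation of the
    current residuals; iteration stops when the largest parameter change
    falls below ``param_tol`` or after ``max_iter`` iterations.  Setting
    ``robust=False`` exposes the plain unweighted fit for comparison.

    Parameters
    ----------
    dwi : DWISeries
        Signal stack; values are floored at a small positive epsilon
        before taking logs.
    mask : bool ndarray, optional
        Voxels to fit; unmasked voxels are zero-filled.  Default: all.

    Returns
    -------
    TensorField

    Raises
    ------
    ValueError
        If the scheme is not well posed (rank-deficient design).
    """
    scheme = dwi.scheme
    if not scheme.is_well_posed():
        raise ValueError("scheme not well-posed: need >=1 b=0 and >=6 unique DW directions")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("scheme not well-posed: rank-deficient design matrix")

    grid = dwi.shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise GridMismatchError(f"mask shape {mask.shape} != image grid {grid}")

    signals = dwi.data[mask]  # (V, N)
    nonzero = signals.max(axis=1) > 0
    n_skipped = int(np.sum(~nonzero))
    if n_skipped:
        logger.warning("skipping %d all-zero voxels inside mask", n_skipped)

    coeffs = np.zeros(grid + (6,), dtype=np.float64)
    s0 = np.zeros(grid, dtype=np.float64)
    evals = np.zeros(grid + (3,), dtype=np.float64)
    n_clamped = 0

    if np.any(nonzero):
        sig = signals[nonzero]
        floor = 1e-6 * sig.max()
        y = np.log(np.maximum(sig, floor))  # (V, N)
        w = np.ones_like(y)
        beta = _batched_wls(X, y, w)
        if robust:
            active = np.ones(beta.shape[0], dtype=bool)
            for _ in range(max_iter):
                if not active.any():
                    break
                resid = y[active] - beta[active] @ X.T  # (Va, N)
                mad = np.median(np.abs(resid - np.median(resid, axis=1, keepdims=True)), axis=1)
                thresh = huber_c * mad  # (Va,)
                absr = np.abs(resid)
                with np.errstate(divide="ignore", invalid="ignore"):
                    w_act = np.where(absr <= thresh[:, None], 1.0, thresh[:, None] / absr)
                w_act[thresh == 0] = 1.0  # perfect fit: keep OLS
                new_beta = _batched_wls(X, y[active], w_act)
                delta = np.max(np.abs(new_beta - beta[active]), axis=1)
                beta[active] = new_beta
                still = delta >= param_tol
                idx = np.flatnonzero(active)
                active[idx[~still]] = False

        vox_coeffs = beta[:, 1:7]
        vox_s0 = np.exp(beta[:, 0])

        mats = np.empty((vox_coeffs.shape[0], 3, 3))
        mats[:, 0, 0] = vox_coeffs[:, 0]
        mats[:, 0, 1] = mats[:, 1, 0] = vox_coeffs[:, 1]
        mats[:, 0, 2] = mats[:, 2, 0] = vox_coeffs[:, 2]
        mats[:, 1, 1] = vox_coeffs[:, 3]
        mats[:, 1, 2] = mats[:, 2, 1] = vox_coeffs[:, 4]
        mats[:, 2, 2] = vox_coeffs[:, 5]
        lam = np.linalg.eigvalsh(mats)[:, ::-1]  # descending
        n_clamped = int(np.sum(lam < 0))
        if n_clamped:
            logger.info("clamped %d negative eigenvalues to zero", n_clamped)
        lam = np.clip(lam, 0.0, None)

        flat_idx = np.flatnonzero(mask.ravel())[nonzero]
        coeffs.reshape(-1, 6)[flat_idx] = vox_coeffs
        s0.reshape(-1)[flat_idx] = vox_s0
        evals.reshape(-1, 3)[flat_idx] = lam

    return TensorField(
        coefficients=coeffs,
        s0=s0,
        eigenvalues=evals,
        voxel_size_mm=dwi.voxel_size_mm,
        n_clamped=n_clamped,
    )


def compute_md(eigenvalues: np.ndarray) -> np.ndarray | float:
    """Mean diffusivity: the arithmetic mean of the three eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=np.float64)
    if lam.shape[-1] != 3:
        raise ValueError("eigenvalues must have last dimension 3")
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite eigenvalues")
    md = lam.mean(axis=-1)
    return float(md) if md.ndim == 0 else md


def compute_fa(eigenvalues: np.ndarray) -> np.ndarray | float:
    """Fractional anisotropy of an eigenvalue triple.

    FA = sqrt( (3/2) * sum_i (lam_i - mean)^2 / sum_i lam_i^2 ),
    in [0, 1] for nonnegative triples; an all-zero triple maps to 0.
    """
    lam = np.asarray(eigenvalues, dtype=np.float64)
    if lam.shape[-1] != 3:
        raise ValueError("eigenvalues must have last dimension 3")
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite eigenvalues")
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    zero = den == 0
    if np.any(zero):
        logger.info("all-zero eigenvalue triples mapped to FA = 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(zero, 0.0, fa)
    fa = np.clip(fa, 0.0, 1.0)
    return float(fa) if fa.ndim == 0 else fa
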