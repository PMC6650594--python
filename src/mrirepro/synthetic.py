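"""Synthetic input generators with known ground truth.

Every downstream stage of the pipeline can be exercised without any
acquired data: a uniform-cylinder phantom with Rician noise and a smooth
nonuniformity field, diffusion-weighted series forward-simulated from
known tensor fields, rater label maps drawn from known confusion
matrices, geometric parcellations, and multi-site measurement panels
with controlled between- and within-scanner variance.

All generators are pure functions of their spec, including the seed.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ImageVolume, LabelMap
from .dti import DiffusionScheme, DWISeries, TensorField

logger = logging.getLogger(__name__)

__all__ = [
    "AcrPhantomSpec",
    "RaterModel",
    "MultiSitePanelSpec",
    "EllipsoidSpec",
    "default_scheme",
    "make_tensor_field",
    "gen_acr_phantom",
    "gen_dwi_series",
    "gen_rater_labelmaps",
    "gen_multisite_panel",
    "gen_geometric_brain",
]


# --------------------------------------------------------------------------
# phantom


@dataclasses.dataclass
class AcrPhantomSpec:
    """Geometry and noise model of the synthetic uniform-cylinder phantom.

    Defaults mimic an 11-slice 256x256 axial acquisition with 250 mm
    field of view and 10 mm slice centres (5 mm slices + 5 mm gaps
    collapsed into spacing).
    """

    grid_shape: tuple[int, int, int] = (256, 256, 11)
    voxel_size_mm: tuple[float, float, float] = (0.977, 0.977, 10.0)
    cylinder_radius_mm: float = 82.0
    signal_level: float = 100.0
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.signal_level <= 0:
            raise ValueError("signal_level must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude must lie in [0, 1)")
        half_fov = (
            min(self.grid_shape[0] * self.voxel_size_mm[0],
                self.grid_shape[1] * self.voxel_size_mm[1]) / 2.0
        )
        if self.cylinder_radius_mm <= 0 or self.cylinder_radius_mm >= half_fov:
            raise ValueError("cylinder must fit inside the in-plane field of view")


def _inplane_radius_mm(shape, voxel_size_mm) -> np.ndarray:
    """Distance of every in-plane voxel centre from the grid centre (mm)."""
    nx, ny = shape[0], shape[1]
    dx, dy = voxel_size_mm[0], voxel_size_mm[1]
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    return np.hypot(x[:, None], y[None, :])


def gen_acr_phantom(spec: AcrPhantomSpec) -> ImageVolume:
    """Simulate a magnitude image of a uniform cylinder in air.

    Inside the cylinder the clean signal is ``signal_level`` modulated by
    a smooth radial quadratic bias field whose (max-min)/(max+min) over
    the cylinder equals ``bias_amplitude``; magnitudes are Rician inside
    and Rayleigh outside (|complex Gaussian| in both cases).
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    r = _inplane_radius_mm(spec.grid_shape, spec.voxel_size_mm)
    inside = r <= spec.cylinder_radius_mm

    clean = np.zeros((nx, ny), dtype=np.float64)
    if spec.bias_amplitude > 0:
        f = (r / spec.cylinder_radius_mm) ** 2
        fin = f[inside]
        fmin, fmax = fin.min(), fin.max()
        B = spec.bias_amplitude
        # bias = 1 - c*f; choose c so (max-min)/(max+min) over cylinder == B
        c = 2.0 * B / ((fmax - fmin) + B * (fmax + fmin))
        bias = 1.0 - c * f
    else:
        bias = np.ones((nx, ny))
    clean[inside] = spec.signal_level * bias[inside]
    clean3d = np.repeat(clean[:, :, None], nz, axis=2)

    if spec.noise_sigma == 0:
        data = clean3d
    else:
        real = clean3d + spec.noise_sigma * rng.standard_normal(clean3d.shape)
        imag = spec.noise_sigma * rng.standard_normal(clean3d.shape)
        data = np.hypot(real, imag)
    return ImageVolume(data=data, voxel_size_mm=spec.voxel_size_mm)


# --------------------------------------------------------------------------
# diffusion


def default_scheme(n_b0: int = 5, n_dw: int = 30, b: float = 1000.0,
                   seed: int = 0) -> DiffusionScheme:
    """A b=0 block plus ``n_dw`` quasi-uniform unit directions at ``b``.

    Directions are placed on a Fibonacci sphere (deterministic for
    ``seed=0``; other seeds apply a random rotation), giving good angular
    coverage for any n >= 6.
    """
    i = np.arange(n_dw)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n_dw
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1 - z * z))
    dirs = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    if seed != 0:
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        dirs = dirs @ q.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dw, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionScheme(bvals=bvals, bvecs=bvecs)


def make_tensor_field(
    coefficients: np.ndarray,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    s0: np.ndarray | float = 1.0,
) -> TensorField:
    """Build a TensorField from raw (..., 6) coefficients (Dxx,Dxy,Dxz,Dyy,Dyz,Dzz)."""
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if coefficients.shape[-1] != 6:
        raise ValueError("coefficients must have last dimension 6")
    tf = TensorField(
        coefficients=coefficients,
        s0=np.broadcast_to(np.asarray(s0, dtype=np.float64), coefficients.shape[:-1]).copy(),
        eigenvalues=np.zeros(coefficients.shape[:-1] + (3,)),
        voxel_size_mm=voxel_size_mm,
    )
    lam = np.linalg.eigvalsh(tf.as_matrices())[..., ::-1]
    tf.eigenvalues = lam
    return tf


def gen_dwi_series(
    tensors: TensorField,
    s0: float | np.ndarray,
    scheme: DiffusionScheme,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DWISeries:
    """Forward-simulate DW magnitudes S = s0 * exp(-b g^T D g) under Rician noise.

    ``noise_sigma = 0`` returns the clean signals exactly.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    s0 = np.asarray(s0, dtype=np.float64)
    if np.any(s0 < 0):
        raise ValueError("s0 must be nonnegative")
    if np.any(tensors.eigenvalues < -1e-12):
        raise ValueError("tensors must be positive semidefinite")

    coeffs = tensors.coefficients.reshape(-1, 6)  # (V, 6)
    b = scheme.bvals
    g = scheme.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    # quadratic-form weights per measurement, matching coefficient order
    W = np.column_stack([gx * gx, 2 * gx * gy, 2 * gx * gz,
                         gy * gy, 2 * gy * gz, gz * gz])  # (N, 6)
    exponent = coeffs @ (b[:, None] * W).T  # (V, N)
    s0_flat = np.broadcast_to(s0, tensors.shape).reshape(-1)
    clean = s0_flat[:, None] * np.exp(-exponent)

    if noise_sigma == 0:
        data = clean
    else:
        rng = np.random.default_rng(seed)
        real = clean + noise_sigma * rng.standard_normal(clean.shape)
        imag = noise_sigma * rng.standard_normal(clean.shape)
        data = np.hypot(real, imag)
    return DWISeries(
        data=data.reshape(tensors.shape + (len(scheme),)),
        scheme=scheme,
        voxel_size_mm=tensors.voxel_size_mm,
    )


# --------------------------------------------------------------------------
# raters


@dataclasses.dataclass
class RaterModel:
    """Per-rater label confusion model.

    ``confusion`` has shape (n_raters, K, K); row = true label, column =
    emitted label; each row sums to 1.
    """

    confusion: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=np.float64)
        if self.confusion.ndim == 2:
            self.confusion = self.confusion[None]
        if self.confusion.ndim != 3 or self.confusion.shape[1] != self.confusion.shape[2]:
            raise ValueError("confusion must have shape (n_raters, K, K)")
        if np.any(self.confusion < 0) or np.any(self.confusion > 1):
            raise ValueError("confusion entries must lie in [0, 1]")
        rowsums = self.confusion.sum(axis=2)
        if np.any(np.abs(rowsums - 1.0) > 1e-12):
            raise ValueError("confusion rows must sum to 1 within 1e-12")

    @property
    def n_raters(self) -> int:
        return self.confusion.shape[0]

    @property
    def n_labels(self) -> int:
        return self.confusion.shape[1]

    @classmethod
    def symmetric(cls, n_raters: int, n_labels: int, diag: float, seed: int = 0) -> "RaterModel":
        """All raters share one matrix: ``diag`` on-diagonal, rest uniform."""
        off = (1.0 - diag) / (n_labels - 1) if n_labels > 1 else 0.0
        m = np.full((n_labels, n_labels), off)
        np.fill_diagonal(m, diag)
        return cls(confusion=np.repeat(m[None], n_raters, axis=0), seed=seed)


def gen_rater_labelmaps(truth: LabelMap, model: RaterModel) -> list[LabelMap]:
    """Draw each rater's map voxelwise from its confusion row of the true label."""
    K = model.n_labels
    t = truth.data.ravel()
    if t.min() < 0 or t.max() >= K:
        raise ValueError(f"truth labels must lie in 0..{K - 1}")
    rng = np.random.default_rng(model.seed)
    maps: list[LabelMap] = []
    for r in range(model.n_raters):
        cdf = np.cumsum(model.confusion[r], axis=1)  # (K, K)
        u = rng.random(t.size)
        emitted = (cdf[t] < u[:, None]).sum(axis=1).astype(np.int32)
        maps.append(
            LabelMap(
                data=emitted.reshape(truth.shape),
                voxel_size_mm=truth.voxel_size_mm,
                labels=truth.labels,
            )
        )
    return maps


# --------------------------------------------------------------------------
# multi-site panels


@dataclasses.dataclass
class MultiSitePanelSpec:
    """Forward model for a multi-scanner measurement panel.

    Each value is ``mu_j * (1 + delta_i + eps_is)`` where ``delta_i`` is a
    scanner effect shared across that scanner's sessions and ``eps_is``
    is a per-session effect.  ``inter_scanner_cv_pct`` is the *pooled*
    across-scanner CV, so the scanner-effect SD is
    sqrt(max(inter^2 - intra^2, 0)) / 100.
    """

    true_values: Mapping[str, float]
    scanner_ids: Sequence[str]
    vendor_of: Mapping[str, str]
    sessions_per_scanner: Mapping[str, int]
    inter_scanner_cv_pct: float = 0.0
    intra_scanner_cv_pct: float = 0.0
    rescan_fraction: float = 0.0
    metric: str = "volume_mm3"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inter_scanner_cv_pct < 0 or self.intra_scanner_cv_pct < 0:
            raise ValueError("CV inputs must be nonnegative")
        if not 0.0 <= self.rescan_fraction <= 1.0:
            raise ValueError("rescan_fraction must lie in [0, 1]")
        for s in self.scanner_ids:
            if s not in self.vendor_of:
                raise ValueError(f"scanner {s!r} has no vendor")
            if self.sessions_per_scanner.get(s, 0) < 1:
                raise ValueError(f"scanner {s!r} needs >= 1 session")
        if any(v <= 0 for v in self.true_values.values()):
            raise ValueError("true values must be positive")
        if self.intra_scanner_cv_pct > self.inter_scanner_cv_pct:
            logger.warning(
                "intra CV (%.3g%%) exceeds inter CV (%.3g%%); "
                "scanner-effect variance floored at zero",
                self.intra_scanner_cv_pct, self.inter_scanner_cv_pct,
            )


def gen_multisite_panel(spec: MultiSitePanelSpec) -> pd.DataFrame:
    """Generate a long-format panel of per-session measurements.

    Returns a DataFrame with columns scanner_id, vendor, session_id,
    is_rescan, label, metric, value.  Negative perturbed values are
    resampled (logged); deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    sigma_b = np.sqrt(max(spec.inter_scanner_cv_pct**2 - spec.intra_scanner_cv_pct**2, 0.0)) / 100.0
    sigma_w = spec.intra_scanner_cv_pct / 100.0

    rows = []
    for scanner in spec.scanner_ids:
        delta = sigma_b * rng.standard_normal() if sigma_b > 0 else 0.0
        n_sess = spec.sessions_per_scanner[scanner]
        n_rescan = int(round(spec.rescan_fraction * n_sess))
        for s in range(n_sess):
            eps = sigma_w * rng.standard_normal() if sigma_w > 0 else 0.0
            factor = 1.0 + delta + eps
            n_resample = 0
            while factor <= 0 and n_resample < 100:
                eps = sigma_w * rng.standard_normal()
                factor = 1.0 + delta + eps
                n_resample += 1
            if n_resample:
                logger.warning("resampled %d nonpositive perturbations", n_resample)
            is_rescan = s >= n_sess - n_rescan
            for label, mu in spec.true_values.items():
                rows.append(
                    {
                        "scanner_id": scanner,
                        "vendor": spec.vendor_of[scanner],
                        "session_id": f"{scanner}-S{s + 1:03d}",
                        "is_rescan": bool(is_rescan),
                        "label": label,
                        "metric": spec.metric,
                        "value": mu * factor,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# geometric parcellations


@dataclasses.dataclass
class EllipsoidSpec:
    """Axis-aligned ellipsoid: centre and semi-axes in mm, plus a label id."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    label: int

    def __post_init__(self) -> None:
        self.center_mm = tuple(float(v) for v in self.center_mm)
        self.semi_axes_mm = tuple(float(v) for v in self.semi_axes_mm)
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if self.label == 0:
            raise ValueError("label 0 is reserved for background")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c


def gen_geometric_brain(
    shape: tuple[int, int, int],
    regions: Sequence[EllipsoidSpec],
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelMap:
    """Label a grid by ellipsoid membership (last containing region wins).

    Voxel centres sit at ``(index + 0.5) * spacing``; 0 is background.
    Regions must lie entirely inside the grid.
    """
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(v) for v in voxel_size_mm)
    extent = [n * v for n, v in zip(shape, spacing)]
    labels_seen = set()
    for reg in regions:
        for c, a, e in zip(reg.center_mm, reg.semi_axes_mm, extent):
            if c - a < 0 or c + a > e:
                raise ValueError(f"ellipsoid (label {reg.label}) exceeds the grid")
        labels_seen.add(reg.label)

    coords = [
        (np.arange(n) + 0.5) * v for n, v in zip(shape, spacing)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    out = np.zeros(shape, dtype=np.int32)
    for reg in regions:
        cx, cy, cz = reg.center_mm
        ax, ay, az = reg.semi_axes_mm
        inside = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0
        out[inside] = reg.label
    return LabelMap(data=out, voxel_size_mm=spacing)
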