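"""ACR-style phantom quality metrics: SNR and percent integral uniformity.

ROIs are constructed deterministically, concentric with the phantom
cylinder axis: a small central signal disc on slices 6-10, a background
region outside the cylinder on slices 2-10, and a large uniformity disc
on slice 7.  Slice indices are 1-based in configuration, following the
ACR counting convention, and converted internally.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .core import GridMismatchError, ImageVolume
from .synthetic import _inplane_radius_mm

__all__ = [
    "AcrRoiConfig",
    "AcrRoiSet",
    "QaResult",
    "build_acr_rois",
    "compute_snr",
    "compute_iu",
    "estimate_shift",
    "align_phantom",
]


@dataclasses.dataclass
class AcrRoiConfig:
    """ROI geometry parameters (areas in mm^2, slices 1-based inclusive)."""

    signal_area_mm2: float = 400.0
    signal_slices: tuple[int, int] = (6, 10)
    background_area_mm2: float = 182.0
    background_slices: tuple[int, int] = (2, 10)
    uniformity_area_mm2: float = 20000.0  # ~200 cm^2, standard large-disc practice
    uniformity_slice: int = 7
    cylinder_radius_mm: float = 82.0
    background_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        for name in ("signal_area_mm2", "background_area_mm2", "uniformity_area_mm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclasses.dataclass
class AcrRoiSet:
    """Boolean masks for the signal, background, and uniformity ROIs."""

    signal_mask: np.ndarray
    background_mask: np.ndarray
    uniformity_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.signal_mask, self.background_mask, self.uniformity_mask)}
        if len(shapes) > 1:
            raise GridMismatchError("ROI masks must share one grid")
        overlap = (
            (self.signal_mask & self.background_mask)
            | (self.signal_mask & self.uniformity_mask)
            | (self.background_mask & self.uniformity_mask)
        )
        if overlap.any():
            raise ValueError("ROI masks must be pairwise disjoint")


@dataclasses.dataclass
class QaResult:
    snr: float
    iu_pct: float
    scanner_id: str = ""
    scan_date: str = ""


def _slice_range(bounds: tuple[int, int], nz: int) -> range:
    """Convert 1-based inclusive slice bounds to a 0-based range."""
    lo, hi = bounds
    if not (1 <= lo <= hi <= nz):
        raise ValueError(f"slice range {bounds} outside 1..{nz}")
    return range(lo - 1, hi)


def _n_voxels(area_mm2: float, voxel_area_mm2: float) -> int:
    return int(round(area_mm2 / voxel_area_mm2))


def build_acr_rois(
    image_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    config: AcrRoiConfig | None = None,
) -> AcrRoiSet:
    """Construct the three QA masks on the given grid.

    Discs are built by taking the n voxels nearest the cylinder axis
    (n = round(target area / voxel area)), which keeps every per-slice
    area within one voxel-area of its target.  The uniformity disc
    excludes the signal-disc voxels on its slice (so masks stay
    disjoint) by growing outward around them; the background region is
    the n voxels nearest the grid corner among those outside the
    cylinder plus a margin.
    """
    config = config or AcrRoiConfig()
    nx, ny, nz = image_shape
    voxel_area = voxel_size_mm[0] * voxel_size_mm[1]
    r = _inplane_radius_mm(image_shape, voxel_size_mm)
    order = np.argsort(r, axis=None, kind="stable")

    def central_disc(n: int, exclude: np.ndarray | None = None) -> np.ndarray:
        mask = np.zeros((nx, ny), dtype=bool)
        if n <= 0:
            return mask
        if exclude is None:
            chosen = order[:n]
        else:
            keep = ~exclude.ravel()[order]
            chosen = order[keep][:n]
        if chosen.size < n:
            raise ValueError("grid too small for requested ROI area")
        mask.ravel()[chosen] = True
        return mask

    n_signal = _n_voxels(config.signal_area_mm2, voxel_area)
    signal_disc = central_disc(n_signal)
    if signal_disc.any() and r[signal_disc].max() > config.cylinder_radius_mm:
        raise ValueError("signal ROI does not fit inside the cylinder")

    n_unif = _n_voxels(config.uniformity_area_mm2, voxel_area)
    unif_slice0 = _slice_range((config.uniformity_slice, config.uniformity_slice), nz)[0]
    sig_slices = _slice_range(config.signal_slices, nz)
    exclude = signal_disc if unif_slice0 in sig_slices else None
    unif_disc = central_disc(n_unif, exclude=exclude)
    if unif_disc.any() and r[unif_disc].max() > config.cylinder_radius_mm:
        raise ValueError("uniformity ROI does not fit inside the cylinder")

    n_bg = _n_voxels(config.background_area_mm2, voxel_area)
    bg_disc = np.zeros((nx, ny), dtype=bool)
    if n_bg > 0:
        # distance from the (0, 0) corner voxel centre, in mm
        x = np.arange(nx) * voxel_size_mm[0]
        y = np.arange(ny) * voxel_size_mm[1]
        corner_dist = np.hypot(x[:, None], y[None, :])
        outside = r > config.cylinder_radius_mm + config.background_margin_mm
        cand = np.flatnonzero(outside.ravel())
        cand = cand[np.argsort(corner_dist.ravel()[cand], kind="stable")]
        if cand.size < n_bg:
            raise ValueError("grid too small for requested background area")
        bg_disc.ravel()[cand[:n_bg]] = True

    signal = np.zeros(image_shape, dtype=bool)
    for z in sig_slices:
        signal[:, :, z] = signal_disc
    background = np.zeros(image_shape, dtype=bool)
    for z in _slice_range(config.background_slices, nz):
        background[:, :, z] = bg_disc
    uniformity = np.zeros(image_shape, dtype=bool)
    uniformity[:, :, unif_slice0] = unif_disc

    return AcrRoiSet(signal_mask=signal, background_mask=background, uniformity_mask=uniformity)


def compute_snr(image: ImageVolume, rois: AcrRoiSet) -> float:
    """mean(signal ROI) / sample SD(background ROI), on magnitude intensities.

    The printed-formula implementation: no Rayleigh correction is applied
    to the background SD.
    """
    if rois.signal_mask.shape != image.shape:
        raise GridMismatchError("ROI grid does not match image")
    bg = image.data[rois.background_mask]
    if bg.size < 2:
        raise ValueError("degenerate background: need >= 2 background voxels")
    sd = float(np.std(bg, ddof=1))
    if sd == 0:
        raise ValueError("degenerate background: zero variance")
    return float(np.mean(image.data[rois.signal_mask]) / sd)


def compute_iu(image: ImageVolume, rois: AcrRoiSet) -> float:
    """Percent integral uniformity over the uniformity ROI.

    Intensities are sorted ascending; ``low``/``high`` are the
    nearest-rank 5th and 95th percentile voxels (the ceil(p*n)-th sorted
    value); IU = 100 * (1 - (high - low) / (high + low)).
    """
    if rois.uniformity_mask.shape != image.shape:
        raise GridMismatchError("ROI grid does not match image")
    vals = np.sort(image.data[rois.uniformity_mask])
    n = vals.size
    if n == 0:
        raise ValueError("uniformity ROI is empty")
    low = vals[max(math.ceil(0.05 * n), 1) - 1]
    high = vals[max(math.ceil(0.95 * n), 1) - 1]
    if high + low == 0:
        raise ValueError("degenerate intensities: high + low = 0")
    return float(100.0 * (1.0 - (high - low) / (high + low)))


def _otsu_threshold(data: np.ndarray, nbins: int = 256) -> float:
    """Classic two-class variance-maximising threshold."""
    hist, edges = np.histogram(data.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(np.float64)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    m0 = np.cumsum(hist * centers)
    total_mean = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (total_mean - m0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between)
    return float(centers[np.argmax(between)])


def estimate_shift(image: ImageVolume, reference: ImageVolume) -> tuple[int, int, int]:
    """Integer-voxel translation taking ``image`` onto ``reference``.

    Foregrounds are thresholded (Otsu-style) and their centres of mass
    compared; raises if either foreground is empty.
    """
    if image.shape != reference.shape:
        raise GridMismatchError("image and reference grids differ")
    shifts = []
    for vol in (image, reference):
        data = vol.data
        if data.max() <= data.min():
            raise ValueError("empty foreground: constant image")
        fg = data > _otsu_threshold(data)
        if not fg.any() or fg.mean() > 0.9:
            raise ValueError("empty foreground: no phantom detected")
        # a real phantom foreground is one coherent blob, not salt-and-pepper
        labeled, n_comp = ndimage.label(fg)
        sizes = np.bincount(labeled.ravel())[1:]
        if sizes.max() < 0.5 * fg.sum():
            raise ValueError("empty foreground: no coherent phantom detected")
        shifts.append(np.array(ndimage.center_of_mass(fg)))
    delta = shifts[1] - shifts[0]
    return tuple(int(round(d)) for d in delta)


def align_phantom(image: ImageVolume, reference: ImageVolume) -> ImageVolume:
    """Apply the integer centre-of-mass shift (no rotation, no interpolation)."""
    shift = estimate_shift(image, reference)
    out = np.zeros_like(image.data)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, s in enumerate(shift):
        n = image.shape[axis]
        if abs(s) >= n:
            return ImageVolume(out, image.voxel_size_mm)
        if s >= 0:
            dst[axis] = slice(s, n)
            src[axis] = slice(0, n - s)
        else:
            dst[axis] = slice(0, n + s)
            src[axis] = slice(-s, n)
    out[tuple(dst)] = image.data[tuple(src)]
    return ImageVolume(out, image.voxel_size_mm)
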