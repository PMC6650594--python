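"""Core data carriers shared across the pipeline stages.

Images are plain numpy arrays plus voxel spacing in millimetres.  All
stages require their inputs to live on identical grids; no resampling is
performed anywhere in this package.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

__all__ = ["ImageVolume", "LabelMap", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two volumes expected on the same grid differ in shape."""


def _as_spacing(voxel_size_mm) -> tuple[float, float, float]:
    spacing = tuple(float(v) for v in voxel_size_mm)
    if len(spacing) != 3:
        raise ValueError("voxel_size_mm must have three components")
    if any(v <= 0 for v in spacing):
        raise ValueError("voxel sizes must be positive")
    return spacing


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities (arbitrary units) or scalar-map values
        (e.g. FA, MD).
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths in millimetres.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires 3D data, got {self.data.ndim}D")
        self.voxel_size_mm = _as_spacing(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclasses.dataclass
class LabelMap:
    """An integer-valued grid with an optional label dictionary.

    ``labels`` maps integer ids to human-readable names; 0 is background
    by convention and need not be listed.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    labels: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("LabelMap data must be integer-valued")
            data = np.round(data).astype(np.int32)
        self.data = data.astype(np.int32, copy=False)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap requires 3D data, got {self.data.ndim}D")
        self.voxel_size_mm = _as_spacing(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def present_labels(self) -> np.ndarray:
        return np.unique(self.data)


def check_same_grid(*shapes_or_objs) -> None:
    """Raise GridMismatchError unless all arguments share one grid shape."""
    shapes = []
    for obj in shapes_or_objs:
        shape = getattr(obj, "shape", obj)
        shapes.append(tuple(shape))
    if len(set(shapes)) > 1:
        raise GridMismatchError(f"grid shapes differ: {shapes}")
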