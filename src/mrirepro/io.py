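"""File formats: NIfTI-1 images, FSL bval/bvec text, CSV panels, YAML configs."""
from __future__ import annotations

import pathlib

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import ImageVolume, LabelMap
from .dti import DiffusionScheme
from .roi import PANEL_COLUMNS, validate_panel

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_scheme",
    "write_scheme",
    "read_panel",
    "write_panel",
    "read_yaml",
    "write_yaml",
]

_BVEC_UNIT_TOL = 1e-3


def write_nifti(obj, path) -> None:
    """Write an ImageVolume, LabelMap, or 4D array as NIfTI-1.

    Label maps are stored with an integer dtype; spacing goes into the
    affine diagonal (RAS, no rotation).
    """
    if isinstance(obj, LabelMap):
        data = obj.data.astype(np.int32)
        spacing = obj.voxel_size_mm
    elif isinstance(obj, ImageVolume):
        data = obj.data.astype(np.float64)
        spacing = obj.voxel_size_mm
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_nifti4d(data: np.ndarray, spacing, path) -> None:
    """Write a 4D stack (e.g. a DW series or tensor volumes)."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError("expected 4D data")
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(spacing) + (1.0,))
    nib.save(img, str(path))


def read_nifti(path, as_labels: bool | None = None):
    """Read a 3D NIfTI as ImageVolume or LabelMap (4D returns (array, spacing)).

    ``as_labels=None`` infers a LabelMap from an integer on-disk dtype.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    if data.ndim == 4:
        return data.astype(np.float64), tuple(float(z) for z in zooms[:3])
    if data.ndim != 3:
        raise ValueError(f"expected 3D or 4D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in zooms[:3])
    if as_labels is None:
        as_labels = np.issubdtype(data.dtype, np.integer)
    if as_labels:
        return LabelMap(data=data.astype(np.int32), voxel_size_mm=spacing)
    return ImageVolume(data=data.astype(np.float64), voxel_size_mm=spacing)


def write_scheme(scheme: DiffusionScheme, bval_path, bvec_path) -> None:
    """Write FSL-dialect bval (1 row) and bvec (3 rows) text files."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:.6g}" for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in scheme.bvecs.T:  # 3 x N
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def read_scheme(bval_path, bvec_path) -> DiffusionScheme:
    """Read an FSL-dialect bval/bvec pair.

    Near-unit b>0 directions (within 1e-3 of unit norm) are normalised;
    zero directions are only allowed at b = 0.
    """
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"count mismatch: {bvals.size} b-values vs {bvecs.shape[0]} directions"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dw = bvals > 0
    bad = dw & (np.abs(norms - 1.0) > _BVEC_UNIT_TOL)
    if bad.any():
        raise ValueError(
            f"non-unit direction(s) at b>0 beyond tolerance: entries {np.flatnonzero(bad)}"
        )
    out = bvecs.copy()
    out[dw] = bvecs[dw] / norms[dw, None]
    return DiffusionScheme(bvals=bvals, bvecs=out)


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a validated scan panel as UTF-8 CSV."""
    validate_panel(panel)
    panel.to_csv(path, index=False, columns=PANEL_COLUMNS + [c for c in panel.columns if c not in PANEL_COLUMNS])


def read_panel(path) -> pd.DataFrame:
    """Read and validate a scan panel CSV."""
    panel = pd.read_csv(
        path,
        dtype={"scanner_id": str, "vendor": str, "session_id": str, "label": str},
    )
    if "is_rescan" in panel.columns:
        panel["is_rescan"] = panel["is_rescan"].astype(bool)
    return validate_panel(panel)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
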