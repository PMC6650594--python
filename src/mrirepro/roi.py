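"""Per-scan measurements: label volumes and ROI means of scalar maps.

These feed the long-format ScanPanel consumed by the reproducibility
engine.  Scalar maps and label maps must live on identical grids; the
pipeline performs no resampling.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GridMismatchError, ImageVolume, LabelMap

logger = logging.getLogger(__name__)

__all__ = ["PANEL_COLUMNS", "label_volumes", "roi_mean_scalar", "assemble_panel", "validate_panel"]

PANEL_COLUMNS = ["scanner_id", "vendor", "session_id", "is_rescan", "label", "metric", "value"]


def label_volumes(
    labels: LabelMap, voxel_size_mm: tuple[float, float, float] | None = None,
    include: Iterable[int] | None = None,
) -> dict[int, float]:
    """Volume of each label in mm^3 (voxel count x voxel volume).

    Background (0) is not reported.  Labels listed in ``include`` but
    absent from the map are reported as 0.
    """
    spacing = voxel_size_mm if voxel_size_mm is not None else labels.voxel_size_mm
    vox_vol = float(np.prod([float(v) for v in spacing]))
    if vox_vol <= 0:
        raise ValueError("voxel spacing must be positive")
    ids, counts = np.unique(labels.data, return_counts=True)
    out = {int(i): float(c) * vox_vol for i, c in zip(ids, counts) if i != 0}
    if include is not None:
        for i in include:
            out.setdefault(int(i), 0.0)
    return out


def roi_mean_scalar(scalar_map: ImageVolume, rois: LabelMap) -> dict[int, float]:
    """Arithmetic mean of the scalar map over each ROI's voxels.

    Empty ROIs are absent from the output.  Background (0) is skipped.
    """
    if scalar_map.shape != rois.shape:
        raise GridMismatchError(
            f"scalar grid {scalar_map.shape} != label grid {rois.shape}"
        )
    out: dict[int, float] = {}
    flat_labels = rois.data.ravel()
    flat_vals = scalar_map.data.ravel()
    sums = np.bincount(flat_labels, weights=flat_vals)
    counts = np.bincount(flat_labels)
    for lab in np.nonzero(counts)[0]:
        if lab == 0:
            continue
        out[int(lab)] = float(sums[lab] / counts[lab])
    return out


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check ScanPanel invariants; returns the panel unchanged."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns: {missing}")
    key = ["scanner_id", "session_id", "label", "metric"]
    if panel.duplicated(subset=key).any():
        dupes = panel[panel.duplicated(subset=key, keep=False)][key]
        raise ValueError(f"duplicate (scanner, session, label, metric) rows:\n{dupes.head()}")
    values = panel["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("panel values must be finite")
    vol = panel["metric"] == "volume_mm3"
    if (panel.loc[vol, "value"] < 0).any():
        raise ValueError("volume values must be nonnegative")
    return panel


def assemble_panel(
    per_scan_measurements: Sequence[Mapping],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble a long-format ScanPanel from per-scan measurement dicts.

    Parameters
    ----------
    per_scan_measurements : sequence of dicts
        Each with keys ``scanner_id``, ``session_id``, ``metric`` and
        ``values`` (a mapping label -> value), and optionally
        ``is_rescan``.
    metadata : DataFrame
        Columns ``scanner_id`` and ``vendor`` (one row per scanner); must
        cover every scan.

    Returns
    -------
    DataFrame with :data:`PANEL_COLUMNS`, validated.
    """
    meta = metadata.drop_duplicates(subset="scanner_id").set_index("scanner_id")
    rows = []
    for scan in per_scan_measurements:
        scanner = scan["scanner_id"]
        if scanner not in meta.index:
            raise ValueError(f"no metadata for scanner {scanner!r}")
        vendor = meta.loc[scanner, "vendor"]
        for label, value in scan["values"].items():
            rows.append(
                {
                    "scanner_id": scanner,
                    "vendor": vendor,
                    "session_id": scan["session_id"],
                    "is_rescan": bool(scan.get("is_rescan", False)),
                    "label": label,
                    "metric": scan["metric"],
                    "value": float(value),
                }
            )
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    return validate_panel(panel)
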