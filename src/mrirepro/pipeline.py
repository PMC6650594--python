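"""End-to-end orchestration: simulate -> QA -> fit -> fuse -> measure -> report.

The pipeline consumes a YAML-backed configuration, derives every stage
seed from the single top-level seed, and writes CSV reports.  Two runs
with the same configuration produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
import pathlib

import numpy as np
import pandas as pd

from . import acr, dti, io, repro, roi, staple, synthetic
from .core import ImageVolume

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scanners": [
        {"id": "A", "vendor": "V1", "sessions": 2},
        {"id": "B", "vendor": "V1", "sessions": 2},
        {"id": "C", "vendor": "V2", "sessions": 2},
    ],
    "phantom": {
        "grid_shape": [96, 96, 11],
        "voxel_size_mm": [0.977, 0.977, 10.0],
        "cylinder_radius_mm": 30.0,
        "signal_level": 100.0,
        "noise_sigma": 2.0,
        "bias_amplitude": 0.05,
        "roi": {
            "signal_area_mm2": 200.0,
            "background_area_mm2": 100.0,
            "uniformity_area_mm2": 2500.0,
            "cylinder_radius_mm": 30.0,
            "background_margin_mm": 3.0,
        },
    },
    "brain": {
        "shape": [24, 24, 12],
        "voxel_size_mm": [2.0, 2.0, 2.0],
        "regions": [
            {"center_mm": [18.0, 24.0, 12.0], "semi_axes_mm": [9.0, 11.0, 7.0], "label": 1},
            {"center_mm": [34.0, 24.0, 12.0], "semi_axes_mm": [8.0, 9.0, 6.0], "label": 2},
        ],
    },
    "dwi": {
        "s0": 1000.0,
        "noise_sigma": 10.0,
        "n_b0": 5,
        "n_dw": 30,
        "b": 1000.0,
        "tensors_by_label": {
            "0": [0.5e-3, 0.5e-3, 0.5e-3],
            "1": [1.7e-3, 0.3e-3, 0.3e-3],
            "2": [1.2e-3, 0.5e-3, 0.4e-3],
        },
        "scanner_effect_cv_pct": 2.0,
    },
    "raters": {"n_raters": 4, "diag": 0.92},
    "staple": {"tol": 1.0e-6, "max_iter": 100, "prior": "pooled"},
    "cv": {"round_decimals": 1},
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline settings (see DEFAULT_CONFIG for the layout)."""

    raw: dict

    def __post_init__(self) -> None:
        cfg = dict(DEFAULT_CONFIG)
        cfg.update(self.raw or {})
        self.raw = cfg
        if not cfg.get("scanners"):
            raise ValueError("config needs at least one scanner")
        for key in ("bval_path", "bvec_path"):
            path = cfg.get(key)
            if path is not None and not pathlib.Path(path).exists():
                raise ValueError(f"configured file does not exist: {path}")
        st = cfg["staple"]
        if not (0 < st["tol"] < 1):
            raise ValueError("staple tol must lie in (0, 1)")
        if st["max_iter"] < 1:
            raise ValueError("staple max_iter must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(io.read_yaml(path))

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))


def _file_hash(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seed(base: int, *parts) -> int:
    """Stable derived seed for one stage invocation."""
    text = ":".join([str(base)] + [str(p) for p in parts])
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


def _diag_tensor(eigs) -> np.ndarray:
    """(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) for an axis-aligned tensor."""
    return np.array([eigs[0], 0.0, 0.0, eigs[1], 0.0, eigs[2]])


def run_pipeline(config: PipelineConfig | dict, out_dir) -> dict:
    """Run the full synthetic pipeline and write report CSVs.

    Writes ``qa.csv`` (per-scan SNR/IU), ``table_qa.csv`` (per-scanner QA
    CVs), ``panel.csv``, ``table_intra.csv``, ``table_labels.csv`` and
    ``summary.csv`` under ``out_dir``.  Returns a manifest with output
    paths, hashes, and per-stage diagnostics.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(config)
    cfg = config.raw
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    # ---- stage: ACR phantom QA ------------------------------------------
    ph = cfg["phantom"]
    roi_cfg = acr.AcrRoiConfig(**ph.get("roi", {}))
    rois = acr.build_acr_rois(tuple(ph["grid_shape"]), tuple(ph["voxel_size_mm"]), roi_cfg)
    qa_rows = []
    for sc in cfg["scanners"]:
        for sess in range(sc["sessions"]):
            spec = synthetic.AcrPhantomSpec(
                grid_shape=tuple(ph["grid_shape"]),
                voxel_size_mm=tuple(ph["voxel_size_mm"]),
                cylinder_radius_mm=ph["cylinder_radius_mm"],
                signal_level=ph["signal_level"],
                noise_sigma=ph["noise_sigma"],
                bias_amplitude=ph["bias_amplitude"],
                seed=_stage_seed(config.seed, "phantom", sc["id"], sess),
            )
            img = synthetic.gen_acr_phantom(spec)
            qa_rows.append(
                {
                    "scanner_id": sc["id"],
                    "scan_date": f"session-{sess + 1}",
                    "snr": acr.compute_snr(img, rois),
                    "iu_pct": acr.compute_iu(img, rois),
                }
            )
    qa = pd.DataFrame(qa_rows)
    qa_path = out_dir / "qa.csv"
    qa.to_csv(qa_path, index=False)

    table_qa = (
        qa.groupby("scanner_id")[["snr", "iu_pct"]]
        .agg(["mean", lambda v: v.std(ddof=1)])
        .pipe(lambda df: df.set_axis(["snr_mean", "snr_sd", "iu_mean", "iu_sd"], axis=1))
        .reset_index()
    )
    table_qa["snr_cv_pct"] = 100.0 * table_qa["snr_sd"] / table_qa["snr_mean"]
    table_qa["iu_cv_pct"] = 100.0 * table_qa["iu_sd"] / table_qa["iu_mean"]
    table_qa_path = out_dir / "table_qa.csv"
    table_qa.to_csv(table_qa_path, index=False)
    manifest["stages"]["acr_qa"] = {"n_scans": len(qa), "out": str(qa_path)}

    # ---- stage: per-scan diffusion + fusion + measurements --------------
    br = cfg["brain"]
    regions = [synthetic.EllipsoidSpec(**r) for r in br["regions"]]
    truth = synthetic.gen_geometric_brain(
        tuple(br["shape"]), regions, tuple(br["voxel_size_mm"])
    )
    n_labels = int(truth.data.max()) + 1

    dw = cfg["dwi"]
    scheme = synthetic.default_scheme(n_b0=dw["n_b0"], n_dw=dw["n_dw"], b=dw["b"])
    base_coeffs = np.zeros(truth.shape + (6,))
    for lab_str, eigs in dw["tensors_by_label"].items():
        base_coeffs[truth.data == int(lab_str)] = _diag_tensor(eigs)

    st = cfg["staple"]
    ra = cfg["raters"]
    measurements = []
    metadata_rows = []
    staple_iters = []
    clamp_counts = []
    for sc in cfg["scanners"]:
        metadata_rows.append({"scanner_id": sc["id"], "vendor": sc["vendor"]})
        rng_sc = np.random.default_rng(_stage_seed(config.seed, "scanner-effect", sc["id"]))
        delta = (dw["scanner_effect_cv_pct"] / 100.0) * rng_sc.standard_normal()
        for sess in range(sc["sessions"]):
            sess_id = f"{sc['id']}-S{sess + 1:03d}"
            tensors = synthetic.make_tensor_field(
                base_coeffs * (1.0 + delta), voxel_size_mm=truth.voxel_size_mm
            )
            series = synthetic.gen_dwi_series(
                tensors,
                s0=dw["s0"],
                scheme=scheme,
                noise_sigma=dw["noise_sigma"],
                seed=_stage_seed(config.seed, "dwi", sc["id"], sess),
            )
            fit = dti.fit_tensor_field(series, mask=truth.data > 0)
            clamp_counts.append(fit.n_clamped)
            fa_map = dti.compute_fa(fit.eigenvalues)
            md_map = dti.compute_md(fit.eigenvalues)

            model = synthetic.RaterModel.symmetric(
                ra["n_raters"], n_labels, ra["diag"],
                seed=_stage_seed(config.seed, "raters", sc["id"], sess),
            )
            rater_maps = synthetic.gen_rater_labelmaps(truth, model)
            fusion = staple.fuse_staple(
                rater_maps, n_labels, max_iter=st["max_iter"], tol=st["tol"]
            )
            staple_iters.append(fusion.n_iterations)
            consensus = fusion.consensus

            vols = roi.label_volumes(consensus)
            fa_vol = ImageVolume(fa_map, truth.voxel_size_mm)
            md_vol = ImageVolume(md_map, truth.voxel_size_mm)
            for metric, values in (
                ("volume_mm3", vols),
                ("FA", roi.roi_mean_scalar(fa_vol, consensus)),
                ("MD", roi.roi_mean_scalar(md_vol, consensus)),
            ):
                measurements.append(
                    {
                        "scanner_id": sc["id"],
                        "session_id": sess_id,
                        "metric": metric,
                        "values": values,
                    }
                )
    metadata = pd.DataFrame(metadata_rows)
    panel = roi.assemble_panel(measurements, metadata)
    panel_path = out_dir / "panel.csv"
    io.write_panel(panel, panel_path)
    manifest["stages"]["measurements"] = {
        "n_rows": len(panel),
        "staple_iterations": staple_iters,
        "clamped_eigenvalues": clamp_counts,
        "out": str(panel_path),
    }

    # ---- stage: reproducibility report ----------------------------------
    paths = write_report(panel, out_dir)
    manifest["stages"]["report"] = {k: str(v) for k, v in paths.items()}
    manifest["hashes"] = {
        p.name: _file_hash(p)
        for p in sorted(out_dir.glob("*.csv"))
    }
    return manifest


def write_report(panel: pd.DataFrame, out_dir) -> dict:
    """Build the CV tables from a panel and write the three report CSVs."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = repro.build_repro_table(panel)

    intra_path = out_dir / "table_intra.csv"
    per_scanner = repro.summarize_across_labels(table, "per-scanner")
    per_scanner.to_csv(intra_path, index=False, float_format="%.6g")

    labels_path = out_dir / "table_labels.csv"
    table.labels.to_csv(labels_path, index=False, float_format="%.6g")

    summary_rows = []
    inter = repro.summarize_across_labels(table, "inter")
    inter.insert(0, "scope", "inter-scanner")
    summary_rows.append(inter)
    mean_intra = repro.summarize_across_labels(table, "mean-intra")
    mean_intra.insert(0, "scope", "mean-intra-scanner")
    summary_rows.append(mean_intra)
    ps = per_scanner.copy()
    ps.insert(0, "scope", "intra-scanner-" + ps.pop("scanner_id"))
    summary_rows.append(ps)
    try:
        vend = repro.summarize_across_labels(table, "vendor")
        vend.insert(0, "scope", "intra-vendor-" + vend.pop("vendor"))
        summary_rows.append(vend)
    except ValueError:
        pass
    summary = pd.concat(summary_rows, ignore_index=True)
    summary_path = out_dir / "summary.csv"
    summary.to_csv(summary_path, index=False, float_format="%.6g")
    return {
        "table_intra": intra_path,
        "table_labels": labels_path,
        "summary": summary_path,
    }
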