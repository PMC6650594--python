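"""Coefficient-of-variation reproducibility summaries.

Computes inter-scanner, intra-scanner, and intra-vendor CVs per label
and metric from a long-format scan panel, plus the across-label and
across-scanner aggregates and inter:intra ratios that make up the
standard multi-site reproducibility report.

Conventions (applied throughout):
  * sample SD (n - 1 denominator);
  * rescan sessions are ordinary sessions in every pool;
  * the inter-scanner CV pools all scans on all scanners directly;
  * "mean intra-scanner" aggregates are unweighted means over scanners;
  * rounding to one decimal happens only in the report layer.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .roi import validate_panel

logger = logging.getLogger(__name__)

__all__ = [
    "cv",
    "cv_from_summary",
    "report_round",
    "ReproTable",
    "SummaryStats",
    "RatioSummary",
    "build_repro_table",
    "summarize_cvs",
    "summarize_across_labels",
    "ratio_summary",
]


def cv(values) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("insufficient replicates: need >= 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    sd = arr.std(ddof=1)
    if sd <= 1e-12 * abs(mean):  # identical values up to float dust
        return 0.0
    return float(100.0 * sd / mean)


def cv_from_summary(mean: float, sd: float) -> float:
    """CV (percent) from already-summarised mean and SD."""
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return float(100.0 * sd / mean)


def report_round(x: float, ndigits: int = 1) -> float:
    """Half-even rounding used by the report layer."""
    return float(np.round(x, ndigits))


@dataclasses.dataclass
class ReproTable:
    """CV tables at every granularity.

    Attributes
    ----------
    inter : DataFrame
        One row per (label, metric): mean, sd, cv_pct, n over all scans.
    intra : DataFrame
        One row per (scanner_id, label, metric) with >= 2 scans.
    vendor : DataFrame
        One row per (vendor, label, metric), pooling the vendor's scans.
    labels : DataFrame
        One row per (label, metric): inter_cv_pct, mean_intra_cv_pct
        (unweighted mean over scanners), ratio_inter_to_mean_intra.
    """

    inter: pd.DataFrame
    intra: pd.DataFrame
    vendor: pd.DataFrame
    labels: pd.DataFrame

    @classmethod
    def from_label_cvs(
        cls,
        labels,
        inter_cv_pct,
        mean_intra_cv_pct,
        metric: str = "volume_mm3",
    ) -> "ReproTable":
        """Build a label-level table directly from known CV columns.

        Used when per-label inter and mean-intra CVs are available (for
        example from a published summary table) without the underlying
        scan-level panel.
        """
        inter_cv = np.asarray(inter_cv_pct, dtype=np.float64)
        intra_cv = np.asarray(mean_intra_cv_pct, dtype=np.float64)
        if not (len(labels) == inter_cv.size == intra_cv.size):
            raise ValueError("labels and CV columns must have equal length")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(intra_cv > 0, inter_cv / intra_cv, np.nan)
        lab = pd.DataFrame(
            {
                "label": list(labels),
                "metric": metric,
                "inter_cv_pct": inter_cv,
                "mean_intra_cv_pct": intra_cv,
                "ratio_inter_to_mean_intra": ratio,
            }
        )
        empty = pd.DataFrame()
        return cls(inter=empty, intra=empty, vendor=empty, labels=lab)


def _group_stats(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    g = df.groupby(keys, sort=True)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out = out[out["n"] >= 2].copy()
    dust = out["sd"] <= 1e-12 * out["mean"].abs()  # identical values up to float dust
    out.loc[dust, "sd"] = 0.0
    out["cv_pct"] = 100.0 * out["sd"] / out["mean"]
    return out


def build_repro_table(panel: pd.DataFrame) -> ReproTable:
    """Compute all CV tables from a validated scan panel.

    Labels present on fewer than two scans are excluded with a warning.
    Scanners with fewer than two scans contribute no intra row; vendors
    with fewer than two scans contribute no vendor row.
    """
    panel = validate_panel(panel)

    counts = panel.groupby(["label", "metric"])["value"].count()
    few = counts[counts < 2]
    if len(few):
        logger.warning("excluding labels with < 2 scans: %s", list(few.index))
        keep = panel.set_index(["label", "metric"]).index.isin(counts[counts >= 2].index)
        panel = panel[keep]
    if panel.empty:
        raise ValueError("panel has no (label, metric) with >= 2 scans")

    inter = _group_stats(panel, ["label", "metric"])
    intra = _group_stats(panel, ["scanner_id", "label", "metric"])
    vendor = _group_stats(panel, ["vendor", "label", "metric"])

    mean_intra = (
        intra.groupby(["label", "metric"])["cv_pct"]
        .mean()
        .rename("mean_intra_cv_pct")
        .reset_index()
    )
    labels = inter[["label", "metric", "cv_pct"]].rename(columns={"cv_pct": "inter_cv_pct"})
    labels = labels.merge(mean_intra, on=["label", "metric"], how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        labels["ratio_inter_to_mean_intra"] = np.where(
            labels["mean_intra_cv_pct"] > 0,
            labels["inter_cv_pct"] / labels["mean_intra_cv_pct"],
            np.nan,
        )
    return ReproTable(inter=inter, intra=intra, vendor=vendor, labels=labels)


@dataclasses.dataclass
class SummaryStats:
    mean_cv_pct: float
    sd_cv_pct: float  # NaN when only one CV enters the summary
    n: int


def summarize_cvs(values) -> SummaryStats:
    """Unweighted mean and sample SD of a collection of CVs."""
    arr = np.asarray(values, dtype=np.float64)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no CV values to summarize")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return SummaryStats(mean_cv_pct=float(arr.mean()), sd_cv_pct=sd, n=int(arr.size))


def summarize_across_labels(table: ReproTable, scope: str) -> pd.DataFrame:
    """Across-label CV summaries at a chosen scope.

    scope:
      * ``"inter"`` — per metric, mean/SD of the per-label inter CVs;
      * ``"per-scanner"`` — per (scanner, metric), mean/SD of that
        scanner's per-label intra CVs;
      * ``"mean-intra"`` — per metric, the unweighted mean over scanners
        of the per-scanner means (and its SD across scanners);
      * ``"vendor"`` — per (vendor, metric), mean/SD of the vendor's
        per-label CVs.
    """
    if scope == "inter":
        src = table.inter if len(table.inter) else table.labels.rename(
            columns={"inter_cv_pct": "cv_pct"}
        )
        rows = [
            {"metric": m, **dataclasses.asdict(summarize_cvs(g["cv_pct"]))}
            for m, g in src.groupby("metric")
        ]
        return pd.DataFrame(rows)
    if scope == "per-scanner":
        if not len(table.intra):
            raise ValueError("table has no intra-scanner rows")
        rows = [
            {"scanner_id": s, "metric": m, **dataclasses.asdict(summarize_cvs(g["cv_pct"]))}
            for (s, m), g in table.intra.groupby(["scanner_id", "metric"])
        ]
        return pd.DataFrame(rows)
    if scope == "mean-intra":
        per_scanner = summarize_across_labels(table, "per-scanner")
        rows = [
            {"metric": m, **dataclasses.asdict(summarize_cvs(g["mean_cv_pct"]))}
            for m, g in per_scanner.groupby("metric")
        ]
        return pd.DataFrame(rows)
    if scope == "vendor":
        if not len(table.vendor):
            raise ValueError("table has no vendor rows")
        rows = [
            {"vendor": v, "metric": m, **dataclasses.asdict(summarize_cvs(g["cv_pct"]))}
            for (v, m), g in table.vendor.groupby(["vendor", "metric"])
        ]
        return pd.DataFrame(rows)
    raise ValueError(f"unknown scope {scope!r}")


@dataclasses.dataclass
class RatioSummary:
    mean_ratio: float
    min_ratio: float
    argmin_label: object
    max_ratio: float
    argmax_label: object


def ratio_summary(table: ReproTable, metric: str | None = None) -> RatioSummary:
    """Mean/min/max of the per-label inter : mean-intra CV ratios."""
    lab = table.labels
    if metric is not None:
        lab = lab[lab["metric"] == metric]
    ratios = lab["ratio_inter_to_mean_intra"].to_numpy(dtype=float)
    labels = lab["label"].to_numpy()
    ok = np.isfinite(ratios)
    if not ok.any():
        raise ValueError("no defined ratios")
    ratios, labels = ratios[ok], labels[ok]
    imin, imax = int(np.argmin(ratios)), int(np.argmax(ratios))
    return RatioSummary(
        mean_ratio=float(ratios.mean()),
        min_ratio=float(ratios[imin]),
        argmin_label=labels[imin],
        max_ratio=float(ratios[imax]),
        argmax_label=labels[imax],
    )
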