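"""Cohort-level orchestration: per-case evaluation, threshold sweeps,
cross-validation pooling, volume binning, metric correlation, and CSV output.

A cohort is driven by a manifest CSV with columns ``case_id, gt_path,
pred_path, fold_id``: each row names a ground-truth mask and either a binary
predicted mask or a probability map in [0, 1].  Probability maps are swept
over ten thresholds (0.1 ... 1.0); the resulting table has one row per
(case, threshold).

Fold statistics are combined as pooled estimates: the pooled mean is the
case-count-weighted mean of fold means, and the pooled SD combines the
within-fold and between-fold variance,

    sd^2 = ( sum (n_i - 1) s_i^2 + n_i (m_i - m)^2 ) / ( sum n_i - 1 ).

Undefined metric values (NaN / inf) are excluded per metric from every
aggregate — a case whose distances are undefined still contributes its
overlap metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import instance_analysis, surface_distances, voxel_metrics
from .volumes_io import (
    LabelVolume,
    ProbabilityVolume,
    binarize,
    check_same_grid,
    read_probability_volume,
)

__all__ = [
    "EvalConfig",
    "DEFAULT_THRESHOLDS",
    "evaluate_case",
    "sweep_thresholds",
    "select_operating_threshold",
    "records_to_frame",
    "fold_summaries",
    "pool_folds",
    "volume_correlation",
    "correlation_matrix",
    "bin_by_volume",
    "dice_tp_aggregate",
    "evaluate_cohort",
    "write_cohort_outputs",
    "CORRELATION_METRICS",
]

#: the ten equally-spaced probability thresholds swept for probability maps
DEFAULT_THRESHOLDS = tuple(round(0.1 * k, 1) for k in range(1, 11))

#: metrics entering the correlation matrix; FPR/FNR are omitted as exact
#: complements of TNR/TPR, and patient-wise recall/precision/F1 are cohort
#: (not per-case) quantities
CORRELATION_METRICS = (
    "dice", "tpr", "tnr", "ppv", "iou", "gce",
    "vs", "ravd",
    "nmi", "voi",
    "cks", "auc", "mcc", "pbd",
    "hd95", "mhd", "assd",
    "ari", "oassd",
)


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation settings shared by every case of a run."""

    connectivity: int = 26
    min_size_voxels: int = 50
    detection_threshold: float = 0.0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    compute_distances: bool = True
    compute_instances: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


def evaluate_case(
    gt: LabelVolume,
    pred_source: LabelVolume | ProbabilityVolume,
    threshold: float | None = None,
    config: EvalConfig = EvalConfig(),
    fold_id: int | str = 0,
) -> dict:
    """Compute the full metric panel for one case at one threshold.

    ``pred_source`` may be a binary mask (used as-is; ``threshold`` recorded
    as NaN) or a probability map, which is binarized at ``threshold`` with the
    >= rule.  Returns a flat dict (one CSV row); undefined metrics are NaN.
    """
    check_same_grid(gt, pred_source)
    if isinstance(pred_source, ProbabilityVolume):
        if threshold is None:
            raise ValueError("a threshold is required for probability-map input")
        pred = binarize(pred_source, threshold)
        pt = float(threshold)
    else:
        pred = pred_source
        pt = math.nan

    row: dict = {
        "case_id": gt.case_id or pred.case_id,
        "fold_id": fold_id,
        "threshold": pt,
        "gt_volume_ml": gt.volume_ml,
        "pred_volume_ml": pred.volume_ml,
    }
    row.update(voxel_metrics.voxel_metric_profile(gt, pred))
    if config.compute_distances:
        row.update(surface_distances.surface_distance_panel(gt, pred))
    if config.compute_instances:
        gt_set = instance_analysis.label_components(
            gt, connectivity=config.connectivity, min_size=config.min_size_voxels
        )
        pred_set = instance_analysis.label_components(
            pred, connectivity=config.connectivity, min_size=config.min_size_voxels
        )
        pairing = instance_analysis.pair_instances(
            gt_set, pred_set, detection_threshold=config.detection_threshold
        )
        whole_dice = row["dice"] if not math.isnan(row["dice"]) else 0.0
        outcome = instance_analysis.case_detection_outcome(
            pairing,
            gt_set,
            pred_set,
            whole_dice=whole_dice,
            case_id=row["case_id"],
            compute_oassd=config.compute_distances,
        )
        row.update(
            patient_detected=outcome.patient_detected,
            n_gt_objects=outcome.n_gt_objects,
            n_detected_gt=outcome.n_detected_gt,
            n_pred_objects=outcome.n_pred_objects,
            n_matched_pred=outcome.n_matched_pred,
            n_fp_objects=outcome.n_fp_objects,
            oassd=outcome.oassd_mm,
        )
    return row


def sweep_thresholds(
    gt: LabelVolume,
    prob: ProbabilityVolume,
    config: EvalConfig = EvalConfig(),
    fold_id: int | str = 0,
) -> list[dict]:
    """One record per probability threshold (0.1 ... 1.0 by default)."""
    return [
        evaluate_case(gt, prob, threshold=t, config=config, fold_id=fold_id)
        for t in config.thresholds
    ]


def records_to_frame(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame.from_records(records)


def select_operating_threshold(records: pd.DataFrame | list[dict]) -> float:
    """Threshold maximizing the mean Dice over the given (validation)
    records; ties go to the lower threshold."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    means = df.groupby("threshold")["dice"].mean().sort_index()
    if means.empty:
        raise ValueError("no records to select a threshold from")
    return float(means.idxmax())  # idxmax returns the first (lowest) maximizer


def _finite(series: pd.Series) -> pd.Series:
    values = pd.to_numeric(series, errors="coerce")
    return values[np.isfinite(values)]


def fold_summaries(
    df: pd.DataFrame,
    metrics: tuple[str, ...] | list[str] | None = None,
) -> pd.DataFrame:
    """Per-fold mean/SD/count for each metric, over defined values only.

    Returns a tidy frame with columns fold_id, metric, n, mean, sd.
    """
    if metrics is None:
        metrics = [m for m in CORRELATION_METRICS if m in df.columns]
    rows = []
    for fold_id, group in df.groupby("fold_id"):
        for metric in metrics:
            vals = _finite(group[metric])
            rows.append(
                {
                    "fold_id": fold_id,
                    "metric": metric,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()) if len(vals) else math.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else math.nan,
                }
            )
    return pd.DataFrame(rows)


def pool_folds(folds: pd.DataFrame) -> pd.DataFrame:
    """Pool per-fold (n, mean, sd) into cohort-level estimates per metric.

    pooled mean = sum(n_i m_i) / sum(n_i);
    pooled sd   = sqrt( (sum (n_i-1) s_i^2 + n_i (m_i - m)^2) / (sum n_i - 1) ).
    With a single fold the pooled values equal the fold values.
    """
    out = []
    for metric, group in folds.groupby("metric"):
        g = group[(group["n"] > 0) & np.isfinite(group["mean"])]
        n_total = int(g["n"].sum())
        if n_total == 0:
            out.append({"metric": metric, "n": 0, "mean": math.nan, "sd": math.nan})
            continue
        mean = float((g["n"] * g["mean"]).sum() / n_total)
        if n_total < 2:
            sd = math.nan
        else:
            within = ((g["n"] - 1) * g["sd"].fillna(0.0) ** 2).sum()
            between = (g["n"] * (g["mean"] - mean) ** 2).sum()
            sd = math.sqrt((within + between) / (n_total - 1))
        out.append({"metric": metric, "n": n_total, "mean": mean, "sd": sd})
    pooled = pd.DataFrame(out)
    pooled["mean_sd"] = [
        f"{m:.2f} ± {s:.2f}" if np.isfinite(m) and np.isfinite(s) else ""
        for m, s in zip(pooled["mean"], pooled["sd"])
    ]
    return pooled


def volume_correlation(df: pd.DataFrame) -> float:
    """Pearson correlation between per-case GT and predicted volumes (ml)."""
    gt = pd.to_numeric(df["gt_volume_ml"])
    pred = pd.to_numeric(df["pred_volume_ml"])
    ok = np.isfinite(gt) & np.isfinite(pred)
    if ok.sum() < 3:
        raise ValueError("volume correlation needs at least 3 cases")
    if gt[ok].std() == 0 or pred[ok].std() == 0:
        return math.nan
    return float(np.corrcoef(gt[ok], pred[ok])[0, 1])


def correlation_matrix(
    df: pd.DataFrame,
    metrics: tuple[str, ...] | list[str] | None = None,
    decimals: int | None = 2,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between per-case metrics.

    Cases with an undefined value are dropped per entry (not cohort-wide);
    entries with fewer than 3 complete pairs, or with zero variance, are NaN.
    Values are rounded to ``decimals`` (2 by default, matching tabular
    presentation); pass ``decimals=None`` for raw values.
    """
    if metrics is None:
        metrics = [m for m in CORRELATION_METRICS if m in df.columns]
    k = len(metrics)
    mat = np.full((k, k), np.nan)
    cols = {m: pd.to_numeric(df[m], errors="coerce").to_numpy(dtype=float) for m in metrics}
    for i, mi in enumerate(metrics):
        for j in range(i, k):
            mj = metrics[j]
            a, b = cols[mi], cols[mj]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3:
                continue
            if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                r = 1.0 if i == j else np.nan
            else:
                r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            mat[i, j] = mat[j, i] = r
    if decimals is not None:
        mat = np.round(mat, decimals)
    return pd.DataFrame(mat, index=list(metrics), columns=list(metrics))


def bin_by_volume(df: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count volume bins with per-bin Dice distribution summaries.

    Cases are ordered by ascending GT volume (ties by case_id) and split into
    ``n_bins`` bins whose counts differ by at most one.  Each bin reports its
    volume range, quartiles of Dice and the number of 1.5*IQR outliers.
    """
    if len(df) < n_bins:
        raise ValueError(f"need at least {n_bins} cases for {n_bins} bins")
    ordered = df.sort_values(["gt_volume_ml", "case_id"], kind="mergesort").reset_index(drop=True)
    splits = np.array_split(np.arange(len(ordered)), n_bins)
    rows = []
    for b, idx in enumerate(splits):
        part = ordered.iloc[idx]
        dice = _finite(part["dice"])
        q1, med, q3 = (
            (dice.quantile(0.25), dice.quantile(0.5), dice.quantile(0.75))
            if len(dice)
            else (math.nan, math.nan, math.nan)
        )
        iqr = q3 - q1
        outliers = (
            int(((dice < q1 - 1.5 * iqr) | (dice > q3 + 1.5 * iqr)).sum())
            if len(dice)
            else 0
        )
        rows.append(
            {
                "bin": b,
                "n_cases": int(len(part)),
                "volume_min_ml": float(part["gt_volume_ml"].min()),
                "volume_max_ml": float(part["gt_volume_ml"].max()),
                "dice_q1": float(q1),
                "dice_median": float(med),
                "dice_q3": float(q3),
                "dice_outliers": outliers,
            }
        )
    return pd.DataFrame(rows)


def dice_tp_aggregate(
    df: pd.DataFrame, detection_threshold: float = 0.0
) -> tuple[float, float]:
    """(mean Dice over all cases, mean Dice over detected cases only).

    Dice-TP restricts to cases whose whole-tumor Dice is strictly above the
    detection threshold — the cases where the model found the tumor.  NaN
    when no case qualifies.
    """
    dice = _finite(df["dice"])
    if dice.empty:
        raise ValueError("no defined Dice values")
    detected = dice[dice > detection_threshold]
    dice_tp = float(detected.mean()) if len(detected) else math.nan
    return float(dice.mean()), dice_tp


def evaluate_cohort(
    manifest: pd.DataFrame | str | Path,
    config: EvalConfig = EvalConfig(),
    sweep: bool = True,
) -> pd.DataFrame:
    """Evaluate every case of a manifest (case_id, gt_path, pred_path, fold_id).

    Prediction files are read as probability maps — a binary mask is a valid
    probability map — and swept over the configured thresholds when ``sweep``
    is true, otherwise evaluated at the highest configured threshold only.
    """
    from .volumes_io import read_label_volume  # local import to keep module load light

    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"case_id", "gt_path", "pred_path", "fold_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")

    records: list[dict] = []
    for row in manifest.itertuples(index=False):
        gt = read_label_volume(row.gt_path, case_id=str(row.case_id))
        prob = read_probability_volume(row.pred_path, case_id=str(row.case_id))
        if sweep:
            records.extend(sweep_thresholds(gt, prob, config=config, fold_id=row.fold_id))
        else:
            records.append(
                evaluate_case(
                    gt, prob, threshold=max(config.thresholds), config=config, fold_id=row.fold_id
                )
            )
    return records_to_frame(records)


def write_cohort_outputs(
    df: pd.DataFrame,
    output_dir: str | Path,
    config: EvalConfig = EvalConfig(),
    threshold: float | None = None,
    n_bins: int = 10,
) -> dict[str, Path]:
    """Write the standard cohort report files and return their paths.

    Produces per-case metrics, per-fold summaries, pooled estimates,
    the metric correlation matrix, and (when the cohort is large enough)
    equal-count volume bins, all as CSV, plus a small YAML run log.
    """
    import yaml

    from . import __version__

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if threshold is None and df["threshold"].notna().any():
        threshold = select_operating_threshold(df.dropna(subset=["threshold"]))
    at_pt = df if threshold is None else df[df["threshold"] == threshold]
    if at_pt.empty:
        at_pt = df

    paths: dict[str, Path] = {}
    paths["cases"] = out / "case_metrics.csv"
    df.to_csv(paths["cases"], index=False)

    folds = fold_summaries(at_pt)
    paths["folds"] = out / "fold_summary.csv"
    folds.to_csv(paths["folds"], index=False)

    paths["pooled"] = out / "pooled_estimates.csv"
    pool_folds(folds).to_csv(paths["pooled"], index=False)

    paths["correlation"] = out / "metric_correlation.csv"
    correlation_matrix(at_pt).to_csv(paths["correlation"])

    if len(at_pt) >= n_bins:
        paths["volume_bins"] = out / "volume_bins.csv"
        bin_by_volume(at_pt, n_bins=n_bins).to_csv(paths["volume_bins"], index=False)

    paths["log"] = out / "run_log.yaml"
    with open(paths["log"], "w") as fh:
        yaml.safe_dump(
            {
                "tool": "segquant",
                "version": __version__,
                "config": config.to_dict(),
                "operating_threshold": threshold,
                "n_records": int(len(df)),
            },
            fh,
            sort_keys=False,
        )
    return paths
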