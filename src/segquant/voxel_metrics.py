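"""Voxel-wise segmentation metrics derived from the 2x2 confusion table.

For a binary ground-truth/prediction pair every overlap, volume,
information-theoretic and agreement metric is an exact function of the four
voxel counts (TP, FP, TN, FN), so the whole panel is computed from a single
pass over the grids.  Undefined values (vanishing denominators, e.g. precision
of an empty prediction) are reported as NaN and excluded from any downstream
aggregation — they are never coerced to 0.

Conventions
-----------
* variation of information (``voi``) is in nats (natural log);
* normalized mutual information (``nmi``) divides mutual information by the
  arithmetic mean of the two marginal entropies;
* ``ravd`` is the *signed* relative volume difference with the ground-truth
  volume as reference, so its range is [-1, inf) and 0 is ideal;
* ``gce`` is kept as a raw fraction (tables often print it scaled by 1e4);
* ``auc`` for a hard binary prediction is (TPR + TNR) / 2, the trapezoidal
  area under the single-operating-point ROC;
* ``pbd`` is +inf (and treated as undefined for pooling) when the prediction
  and ground truth share no mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .volumes_io import LabelVolume, ProbabilityVolume, check_same_grid

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "overlap_rates",
    "overlap_scores",
    "gce",
    "volume_scores",
    "information_scores",
    "agreement_scores",
    "probabilistic_distance",
    "voxel_metric_profile",
    "VOXEL_METRIC_NAMES",
]

#: metric keys produced by :func:`voxel_metric_profile`, in reporting order
VOXEL_METRIC_NAMES = (
    "tpr", "tnr", "fpr", "fnr", "ppv",
    "dice", "iou", "gce",
    "vs", "ravd",
    "nmi", "voi",
    "cks", "auc", "mcc", "ari",
    "pbd",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts of the joint ground-truth/prediction membership."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def gt_positives(self) -> int:
        return self.tp + self.fn

    @property
    def pred_positives(self) -> int:
        return self.tp + self.fp


def confusion_counts(gt: LabelVolume, pred: LabelVolume) -> ConfusionCounts:
    """Count TP/FP/TN/FN voxels for two binary masks on the same grid."""
    check_same_grid(gt, pred)
    g = gt.grid.astype(bool)
    p = pred.grid.astype(bool)
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    tn = g.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def overlap_rates(c: ConfusionCounts) -> tuple[float, float, float, float, float]:
    """(TPR, TNR, FPR, FNR, PPV); NaN where the defining denominator is zero."""
    tpr = _ratio(c.tp, c.tp + c.fn)
    tnr = _ratio(c.tn, c.tn + c.fp)
    fpr = _ratio(c.fp, c.fp + c.tn)
    fnr = _ratio(c.fn, c.tp + c.fn)
    ppv = _ratio(c.tp, c.tp + c.fp)
    return tpr, tnr, fpr, fnr, ppv


def overlap_scores(c: ConfusionCounts) -> tuple[float, float]:
    """(Dice, IoU); undefined only when both masks are empty."""
    dice = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    iou = _ratio(c.tp, c.tp + c.fp + c.fn)
    return dice, iou


def gce(c: ConfusionCounts) -> float:
    """Global consistency error: min of the two directed refinement errors / n.

    E12 measures how well the prediction's regions refine the ground truth's
    and vice versa for E21; a term with a vanishing denominator contributes 0
    (a region absent from one partition imposes no refinement error).
    """
    if c.n == 0:
        raise ValueError("empty grid")

    def term(a: int, b: int) -> float:
        return 2.0 * a * b / (a + b) if (a + b) > 0 else 0.0

    e12 = term(c.tp, c.fn) + term(c.fp, c.tn)
    e21 = term(c.tp, c.fp) + term(c.fn, c.tn)
    return min(e12, e21) / c.n


def volume_scores(c: ConfusionCounts) -> tuple[float, float]:
    """(volumetric similarity, signed relative volume difference).

    ``vs = 1 - |fn - fp| / (2 tp + fp + fn)``;
    ``ravd = (pred_volume - gt_volume) / gt_volume`` (NaN for empty GT).
    """
    vs = _ratio(2 * c.tp + c.fp + c.fn - abs(c.fn - c.fp), 2 * c.tp + c.fp + c.fn)
    ravd = _ratio(c.pred_positives - c.gt_positives, c.gt_positives)
    if c.gt_positives == 0:
        ravd = math.nan
    return vs, ravd


def _entropy(probs: np.ndarray) -> float:
    return float(-xlogy(probs, probs).sum())


def information_scores(c: ConfusionCounts) -> tuple[float, float]:
    """(NMI, VOI) treating the two masks as 2-cluster partitions of the grid.

    Entropies use natural log; zero-probability cells contribute nothing.
    NMI is undefined when either partition has zero entropy (constant mask).
    """
    if c.n == 0:
        raise ValueError("empty grid")
    n = float(c.n)
    joint = np.array([c.tp, c.fn, c.fp, c.tn], dtype=np.float64) / n
    h_gt = _entropy(np.array([c.gt_positives, c.n - c.gt_positives]) / n)
    h_pred = _entropy(np.array([c.pred_positives, c.n - c.pred_positives]) / n)
    h_joint = _entropy(joint)
    mi = h_gt + h_pred - h_joint
    voi = max(h_gt + h_pred - 2.0 * mi, 0.0)
    mean_h = 0.5 * (h_gt + h_pred)
    nmi = mi / mean_h if h_gt > 0 and h_pred > 0 else math.nan
    return nmi, voi


def _comb2(k: int) -> int:
    return k * (k - 1) // 2


def agreement_scores(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Cohen's kappa, AUC, Matthews correlation, adjusted Rand index).

    All four are exact functions of the 2x2 contingency table.  The MCC equals
    the Pearson (phi) correlation of the two flattened binary grids.  The ARI
    uses the pair-counting formula; when its normalizer degenerates (both
    partitions constant) the value is 1.0, matching the usual clustering
    convention that identical trivial partitions agree perfectly.
    """
    if c.n <= 1:
        raise ValueError("need at least 2 voxels")
    n = c.n
    po = (c.tp + c.tn) / n
    pe = (c.gt_positives * c.pred_positives + (c.tn + c.fp) * (c.tn + c.fn)) / (n * n)
    cks = (po - pe) / (1.0 - pe) if pe < 1.0 else math.nan

    tpr = _ratio(c.tp, c.tp + c.fn)
    tnr = _ratio(c.tn, c.tn + c.fp)
    auc = 0.5 * (tpr + tnr)

    denom2 = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2) if denom2 > 0 else math.nan

    index = _comb2(c.tp) + _comb2(c.fn) + _comb2(c.fp) + _comb2(c.tn)
    sum_a = _comb2(c.gt_positives) + _comb2(c.n - c.gt_positives)
    sum_b = _comb2(c.pred_positives) + _comb2(c.n - c.pred_positives)
    total = _comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        ari = 1.0
    else:
        ari = (index - expected) / (max_index - expected)
    return cks, auc, mcc, ari


def probabilistic_distance(gt: LabelVolume, pred: LabelVolume | ProbabilityVolume) -> float:
    """Probabilistic distance between the GT mask and a (possibly fuzzy) prediction.

    ``PBD = sum |g - p| / (2 * sum g*p)`` over all voxels.  For a binary
    prediction this reduces to ``(FP + FN) / (2 TP)``.  With no shared mass
    the distance is +inf and is excluded from pooled statistics.
    """
    check_same_grid(gt, pred)
    g = gt.grid.astype(np.float64)
    p = np.asarray(pred.grid, dtype=np.float64)
    overlap = float((g * p).sum())
    if overlap == 0.0:
        return math.inf
    return float(np.abs(g - p).sum()) / (2.0 * overlap)


def voxel_metric_profile(
    gt: LabelVolume,
    pred: LabelVolume,
    pbd_source: ProbabilityVolume | None = None,
) -> dict[str, float]:
    """Compute the full confusion-derived metric panel for one case.

    Returns a dict keyed by :data:`VOXEL_METRIC_NAMES`; NaN (or +inf for
    ``pbd``) marks an undefined value.  ``pbd_source`` optionally supplies the
    raw probability map for the probabilistic distance; by default the same
    binarized mask used for every other metric is used.
    """
    c = confusion_counts(gt, pred)
    tpr, tnr, fpr, fnr, ppv = overlap_rates(c)
    dice, iou = overlap_scores(c)
    vs, ravd = volume_scores(c)
    nmi, voi = information_scores(c)
    cks, auc, mcc, ari = agreement_scores(c)
    pbd = probabilistic_distance(gt, pbd_source if pbd_source is not None else pred)
    return {
        "tpr": tpr, "tnr": tnr, "fpr": fpr, "fnr": fnr, "ppv": ppv,
        "dice": dice, "iou": iou, "gce": gce(c),
        "vs": vs, "ravd": ravd,
        "nmi": nmi, "voi": voi,
        "cks": cks, "auc": auc, "mcc": mcc, "ari": ari,
        "pbd": pbd,
    }
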