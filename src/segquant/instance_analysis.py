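"""Connected-component (lesion-wise) analysis and detection metrics.

Tumor foci are extracted as 3-D connected components (26-connectivity by
default, configurable to 6 or 18), and components below a minimum voxel count
— 50 voxels by default — are discarded from both the ground truth and the
prediction, so that sub-resolution specks count neither as targets nor as
false alarms.

Predicted and ground-truth foci are then paired: every predicted instance is
assigned to the ground-truth instance with which its pairwise Dice is maximal
(ties broken toward the larger GT instance, then the lower GT id) and the
assignment is kept only when that Dice exceeds the detection threshold
(strictly greater than 0 by default).  Several predicted objects may hit the
same GT object — a fragmented but correct prediction is not punished as false
positives — while each predicted object is counted exactly once.

Detection quality is summarized patient-wise (one entity per case) and
object-wise (each focus of a multifocal tumor counted separately), together
with the average number of unmatched predicted objects per patient (FPPP) and
the object-wise average symmetric surface distance (OASSD) over matched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import surface_distances
from .volumes_io import LabelVolume, check_same_grid

__all__ = [
    "Instance",
    "InstanceSet",
    "InstancePairing",
    "CaseDetection",
    "DetectionSummary",
    "label_components",
    "pair_instances",
    "case_detection_outcome",
    "cohort_detection_summary",
    "oassd",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class Instance:
    """One tumor focus: a connected component of a binary mask."""

    instance_id: int
    voxel_count: int
    volume_ml: float


@dataclass
class InstanceSet:
    """Post-filter connected components of one mask.

    ``labels`` is the full labeled grid (0 = background); only surviving
    component ids appear in ``instances``.
    """

    instances: list[Instance]
    labels: np.ndarray = field(repr=False)
    spacing: tuple[float, float, float]
    connectivity: int
    min_size_voxels: int

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def ids(self) -> list[int]:
        return [inst.instance_id for inst in self.instances]

    def by_id(self, instance_id: int) -> Instance:
        for inst in self.instances:
            if inst.instance_id == instance_id:
                return inst
        raise KeyError(instance_id)

    def instance_mask(self, instance_id: int) -> LabelVolume:
        return LabelVolume(
            grid=(self.labels == instance_id).astype(np.uint8),
            spacing=self.spacing,
        )


@dataclass
class InstancePairing:
    """GT<->prediction component matching for one case."""

    matches: list[tuple[int, int, float]]  # (gt_id, pred_id, pair_dice)
    unmatched_gt: list[int]
    unmatched_pred: list[int]
    detection_threshold: float

    @property
    def detected_gt_ids(self) -> list[int]:
        return sorted({gt_id for gt_id, _, _ in self.matches})


def label_components(
    v: LabelVolume,
    connectivity: int = 26,
    min_size: int = 50,
) -> InstanceSet:
    """Extract connected components and discard those below ``min_size`` voxels."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_raw = ndimage.label(v.grid, structure=structure)
    instances: list[Instance] = []
    if n_raw:
        counts = np.bincount(labels.ravel())
        voxel_ml = float(np.prod(v.spacing)) / 1000.0
        for cid in range(1, n_raw + 1):
            count = int(counts[cid]) if cid < len(counts) else 0
            if count >= min_size:
                instances.append(
                    Instance(instance_id=cid, voxel_count=count, volume_ml=count * voxel_ml)
                )
            else:
                labels[labels == cid] = 0
    return InstanceSet(
        instances=instances,
        labels=labels,
        spacing=v.spacing,
        connectivity=connectivity,
        min_size_voxels=min_size,
    )


def _pairwise_overlaps(gt: InstanceSet, pred: InstanceSet) -> dict[tuple[int, int], int]:
    """Overlap voxel counts for every co-occurring (gt_id, pred_id) pair."""
    both = (gt.labels > 0) & (pred.labels > 0)
    if not both.any():
        return {}
    g = gt.labels[both]
    p = pred.labels[both]
    pairs, counts = np.unique(np.stack([g, p], axis=1), axis=0, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(pairs, counts)}


def pair_instances(
    gt: InstanceSet,
    pred: InstanceSet,
    detection_threshold: float = 0.0,
) -> InstancePairing:
    """Assign each predicted focus to its best-overlapping GT focus.

    The assignment is kept only if the pairwise Dice is strictly greater than
    ``detection_threshold``; unassigned predicted foci are false positives.
    Deterministic under relabeling: ties in pairwise Dice are broken toward
    the larger GT instance, then the lower GT id.
    """
    overlaps = _pairwise_overlaps(gt, pred)
    gt_sizes = {inst.instance_id: inst.voxel_count for inst in gt.instances}
    pred_sizes = {inst.instance_id: inst.voxel_count for inst in pred.instances}

    matches: list[tuple[int, int, float]] = []
    unmatched_pred: list[int] = []
    for pred_id in sorted(pred_sizes):
        best: tuple[float, int, int] | None = None  # (dice, gt_size, -gt_id)
        for gt_id in sorted(gt_sizes):
            ovl = overlaps.get((gt_id, pred_id), 0)
            dice = 2.0 * ovl / (gt_sizes[gt_id] + pred_sizes[pred_id])
            key = (dice, gt_sizes[gt_id], -gt_id)
            if best is None or key > best:
                best = key
        if best is not None and best[0] > detection_threshold:
            matches.append((-best[2], pred_id, best[0]))
        else:
            unmatched_pred.append(pred_id)

    matched_gt = {gt_id for gt_id, _, _ in matches}
    unmatched_gt = [gt_id for gt_id in sorted(gt_sizes) if gt_id not in matched_gt]
    return InstancePairing(
        matches=matches,
        unmatched_gt=unmatched_gt,
        unmatched_pred=unmatched_pred,
        detection_threshold=detection_threshold,
    )


@dataclass
class CaseDetection:
    """Per-case detection bookkeeping feeding the cohort summary."""

    case_id: str
    patient_detected: bool
    has_prediction: bool  # at least one post-filter predicted object
    n_gt_objects: int
    n_detected_gt: int
    n_pred_objects: int
    n_matched_pred: int
    n_fp_objects: int
    oassd_mm: float  # NaN when no matched pair


def case_detection_outcome(
    pairing: InstancePairing,
    gt: InstanceSet,
    pred: InstanceSet,
    whole_dice: float,
    case_id: str = "",
    compute_oassd: bool = True,
) -> CaseDetection:
    """Summarize one case: a patient counts as detected iff the whole-tumor
    Dice exceeds the detection threshold."""
    return CaseDetection(
        case_id=case_id,
        patient_detected=bool(whole_dice > pairing.detection_threshold),
        has_prediction=len(pred) > 0,
        n_gt_objects=len(gt),
        n_detected_gt=len(pairing.detected_gt_ids),
        n_pred_objects=len(pred),
        n_matched_pred=len(pairing.matches),
        n_fp_objects=len(pairing.unmatched_pred),
        oassd_mm=oassd(pairing, gt, pred) if compute_oassd else float("nan"),
    )


def oassd(pairing: InstancePairing, gt: InstanceSet, pred: InstanceSet) -> float:
    """Mean pairwise ASSD (mm) over matched (GT, prediction) object pairs;
    NaN when nothing was matched."""
    if not pairing.matches:
        return float("nan")
    values = []
    for gt_id, pred_id, _ in pairing.matches:
        gs = surface_distances.extract_surface(gt.instance_mask(gt_id))
        ps = surface_distances.extract_surface(pred.instance_mask(pred_id))
        _, assd = surface_distances.distance_statistics(gs, ps)
        values.append(assd)
    return float(np.mean(values))


@dataclass
class DetectionSummary:
    """Patient-wise and object-wise detection metrics over a cohort.

    Recall/precision/F1 are percentages in [0, 100]; FPPP is the mean number
    of false-positive objects per patient; OASSD (mm) averages the per-case
    OASSD over cases where it is defined.
    """

    pw_recall: float
    pw_precision: float
    pw_f1: float
    ow_recall: float
    ow_precision: float
    ow_f1: float
    fppp: float
    oassd_mm: float
    n_cases: int


def _f1(precision: float, recall: float) -> float:
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def cohort_detection_summary(cases: list[CaseDetection]) -> DetectionSummary:
    """Aggregate per-case outcomes into the cohort detection panel.

    Patient-wise precision counts a patient against precision when it has at
    least one predicted object but the tumor itself was not detected
    (a spurious-only prediction).
    """
    if not cases:
        raise ValueError("empty cohort")
    n = len(cases)
    detected = sum(c.patient_detected for c in cases)
    spurious_only = sum((not c.patient_detected) and c.has_prediction for c in cases)

    pw_recall = 100.0 * detected / n
    pw_den = detected + spurious_only
    pw_precision = 100.0 * detected / pw_den if pw_den > 0 else float("nan")

    total_gt = sum(c.n_gt_objects for c in cases)
    total_pred = sum(c.n_pred_objects for c in cases)
    ow_recall = 100.0 * sum(c.n_detected_gt for c in cases) / total_gt if total_gt else float("nan")
    ow_precision = (
        100.0 * sum(c.n_matched_pred for c in cases) / total_pred if total_pred else float("nan")
    )

    fppp = float(np.mean([c.n_fp_objects for c in cases]))
    oassd_values = [c.oassd_mm for c in cases if np.isfinite(c.oassd_mm)]
    oassd_mm = float(np.mean(oassd_values)) if oassd_values else float("nan")

    return DetectionSummary(
        pw_recall=pw_recall,
        pw_precision=pw_precision,
        pw_f1=_f1(pw_precision, pw_recall),
        ow_recall=ow_recall,
        ow_precision=ow_precision,
        ow_f1=_f1(ow_precision, ow_recall),
        fppp=fppp,
        oassd_mm=oassd_mm,
        n_cases=n,
    )
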