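"""Mask-derived clinical report features: volume, focality, laterality and
atlas-based location profiles.

These features assume the mask (and any atlas label volume) has already been
registered to a common reference space whose midsagittal plane is a known
grid plane — e.g. the symmetric MNI ICBM2009a atlas.  Registration itself is
out of scope here; this module only measures.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .instance_analysis import InstanceSet, label_components
from .volumes_io import LabelVolume, check_same_grid

__all__ = [
    "FeatureReport",
    "tumor_volume_ml",
    "focality",
    "laterality",
    "location_profile",
    "compute_feature_report",
    "write_report",
]

#: minority hemispheric share (percent) above which a tumor is considered to
#: cross the midline
MIDLINE_CROSSING_PERCENT = 1.0


@dataclass
class FeatureReport:
    """Standardized tumor description computed from one binary mask."""

    case_id: str
    volume_ml: float
    focus_count: int
    multifocal: bool
    left_share: float  # percent of foreground voxels; NaN for an empty mask
    right_share: float
    midline_crossing: bool
    location_profile: dict[str, float] = field(default_factory=dict)


def tumor_volume_ml(v: LabelVolume) -> float:
    """Foreground volume in ml (voxel count x voxel volume / 1000)."""
    return v.volume_ml


def focality(instances: InstanceSet) -> tuple[int, bool]:
    """(number of post-filter foci, multifocal flag: at least two foci)."""
    count = len(instances)
    return count, count >= 2


def laterality(
    v: LabelVolume,
    midline_axis: int = 0,
    midline_position: float | None = None,
) -> tuple[float, float, bool]:
    """Hemispheric split of the tumor about a grid-aligned midsagittal plane.

    ``left`` collects foreground voxels with index strictly below
    ``midline_position`` along ``midline_axis``; voxels exactly on the
    midline count with the right side.  Shares are percentages of the
    foreground and sum to 100.  The tumor crosses the midline when the
    minority share reaches :data:`MIDLINE_CROSSING_PERCENT`.
    Empty mask: shares are NaN and crossing is False.
    """
    if midline_position is None:
        midline_position = v.shape[midline_axis] / 2.0
    total = v.foreground_count
    if total == 0:
        return math.nan, math.nan, False
    coords = np.argwhere(v.grid)[:, midline_axis]
    left = int((coords < midline_position).sum())
    right = total - left
    left_share = 100.0 * left / total
    right_share = 100.0 * right / total
    crossing = min(left_share, right_share) >= MIDLINE_CROSSING_PERCENT
    return left_share, right_share, crossing


def location_profile(
    v: LabelVolume,
    atlas: np.ndarray,
    names: dict[int, str] | pd.DataFrame,
) -> dict[str, float]:
    """Percent of tumor volume inside each named atlas structure.

    ``atlas`` is an integer label volume on the same grid (0 = background);
    ``names`` maps label -> structure name (or a DataFrame with columns
    ``label`` and ``name``).  Tumor voxels in label 0 or in labels missing
    from ``names`` are reported under ``"unlabeled"``.  Percentages sum to
    100 for a nonempty tumor.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != v.shape:
        raise ValueError(f"atlas shape {atlas.shape} does not match mask shape {v.shape}")
    if isinstance(names, pd.DataFrame):
        names = {int(r.label): str(r.name) for r in names.itertuples(index=False)}
    total = v.foreground_count
    profile: dict[str, float] = {name: 0.0 for name in names.values()}
    profile["unlabeled"] = 0.0
    if total == 0:
        return profile
    labels_in_tumor = atlas[v.grid.astype(bool)]
    values, counts = np.unique(labels_in_tumor, return_counts=True)
    for label, count in zip(values, counts):
        name = names.get(int(label), "unlabeled") if label != 0 else "unlabeled"
        profile[name] = profile.get(name, 0.0) + 100.0 * count / total
    return profile


def compute_feature_report(
    v: LabelVolume,
    atlas: np.ndarray | None = None,
    names: dict[int, str] | pd.DataFrame | None = None,
    connectivity: int = 26,
    min_size: int = 50,
    midline_axis: int = 0,
    midline_position: float | None = None,
) -> FeatureReport:
    """Compute the full feature set for one mask (optionally with an atlas)."""
    instances = label_components(v, connectivity=connectivity, min_size=min_size)
    count, multifocal = focality(instances)
    left, right, crossing = laterality(v, midline_axis, midline_position)
    profile = (
        location_profile(v, atlas, names) if atlas is not None and names is not None else {}
    )
    return FeatureReport(
        case_id=v.case_id,
        volume_ml=tumor_volume_ml(v),
        focus_count=count,
        multifocal=multifocal,
        left_share=left,
        right_share=right,
        midline_crossing=crossing,
        location_profile=profile,
    )


def write_report(report: FeatureReport, directory: str | Path) -> tuple[Path, Path]:
    """Write the report as CSV (one feature per row) and nested JSON.

    Field order is deterministic so reruns are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = report.case_id or "case"
    csv_path = directory / f"{stem}_report.csv"
    json_path = directory / f"{stem}_report.json"

    def fmt(x: float) -> str:
        return "undefined" if isinstance(x, float) and math.isnan(x) else f"{x:.6g}"

    rows = [
        ("case_id", report.case_id),
        ("volume_ml", fmt(report.volume_ml)),
        ("focus_count", str(report.focus_count)),
        ("multifocal", str(report.multifocal)),
        ("left_share_percent", fmt(report.left_share)),
        ("right_share_percent", fmt(report.right_share)),
        ("midline_crossing", str(report.midline_crossing)),
    ]
    for name in sorted(report.location_profile):
        rows.append((f"location/{name}", fmt(report.location_profile[name])))
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["feature", "value"])
        writer.writerows(rows)

    payload = {
        "case_id": report.case_id,
        "volume_ml": None if math.isnan(report.volume_ml) else report.volume_ml,
        "focality": {"focus_count": report.focus_count, "multifocal": report.multifocal},
        "laterality": {
            "left_share_percent": None if math.isnan(report.left_share) else report.left_share,
            "right_share_percent": None if math.isnan(report.right_share) else report.right_share,
            "midline_crossing": report.midline_crossing,
        },
        "location_profile": {k: report.location_profile[k] for k in sorted(report.location_profile)},
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return csv_path, json_path
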