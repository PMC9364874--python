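"""Reading, writing and grid handling for 3-D tumor masks and probability maps.

Volumes are compared in the voxel space of a shared grid: two inputs must have
identical shapes and (within tolerance) identical voxel spacing.  No resampling
or registration is performed here — masks are expected to already live on a
common grid, as produced by an upstream segmentation pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "LabelVolume",
    "ProbabilityVolume",
    "GridMismatchError",
    "read_label_volume",
    "read_probability_volume",
    "write_label_volume",
    "write_probability_volume",
    "binarize",
    "check_same_grid",
]

#: relative tolerance (mm) when comparing voxel spacings of two grids
SPACING_RTOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes do not live on the same voxel grid."""


@dataclass
class LabelVolume:
    """A 3-D binary mask with physical voxel spacing.

    Parameters
    ----------
    grid :
        3-D array with values in {0, 1}; 1 marks a tumor (foreground) voxel.
    spacing :
        Voxel size in mm along each axis.
    case_id :
        Free-text identifier carried into reports.
    affine :
        Optional 4x4 voxel-to-world matrix, preserved for round-trip writing.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = ""
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got {self.grid.ndim}-D")
        vals = np.unique(self.grid)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("label grid must contain only 0/1 values")
        self.grid = self.grid.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    @property
    def volume_ml(self) -> float:
        """Foreground volume in milliliters (1 ml = 1000 mm^3)."""
        return self.foreground_count * self.voxel_volume_mm3 / 1000.0


@dataclass
class ProbabilityVolume:
    """A 3-D map of foreground probabilities in [0, 1] on a physical grid."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = ""
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got {self.grid.ndim}-D")
        if self.grid.min() < 0.0 or self.grid.max() > 1.0:
            raise ValueError("probability grid must lie in [0, 1]")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple, np.ndarray]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D content, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    return data, spacing, img.affine


def read_label_volume(path: str | os.PathLike, case_id: str | None = None) -> LabelVolume:
    """Read a NIfTI mask; any strictly positive value maps to foreground.

    Multi-label inputs collapse to a single binary foreground class, since the
    whole tumor extent is evaluated as one entity.
    """
    data, spacing, affine = _load_nifti(path)
    grid = (data > 0).astype(np.uint8)
    name = case_id if case_id is not None else _stem(path)
    return LabelVolume(grid=grid, spacing=spacing, case_id=name, affine=affine)


def read_probability_volume(path: str | os.PathLike, case_id: str | None = None) -> ProbabilityVolume:
    """Read a NIfTI probability map with values in [0, 1] (1e-6 clip tolerance)."""
    data, spacing, affine = _load_nifti(path)
    data = np.asarray(data, dtype=np.float64)
    if data.min() < -1e-6 or data.max() > 1.0 + 1e-6:
        raise ValueError(
            f"{path}: values outside [0, 1] (range [{data.min():g}, {data.max():g}]); "
            "not a probability map"
        )
    grid = np.clip(data, 0.0, 1.0)
    name = case_id if case_id is not None else _stem(path)
    return ProbabilityVolume(grid=grid, spacing=spacing, case_id=name, affine=affine)


def _stem(path: str | os.PathLike) -> str:
    base = os.path.basename(str(path))
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            return base[: -len(suffix)]
    return os.path.splitext(base)[0]


def _affine_or_diag(v: LabelVolume | ProbabilityVolume) -> np.ndarray:
    if v.affine is not None:
        return v.affine
    return np.diag(list(v.spacing) + [1.0])


def write_label_volume(v: LabelVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(v.grid.astype(np.uint8), _affine_or_diag(v))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def write_probability_volume(v: ProbabilityVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(v.grid.astype(np.float32), _affine_or_diag(v))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def binarize(p: ProbabilityVolume, t: float) -> LabelVolume:
    """Threshold a probability map: a voxel is foreground iff probability >= t.

    Valid thresholds lie in (0, 1]; with the ">=" rule t = 1.0 keeps exactly
    the voxels with probability 1, making a sweep well defined at the top end
    (t = 0 would mark the entire grid foreground and is rejected).
    """
    if not (0.0 < t <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {t}")
    grid = (p.grid >= t).astype(np.uint8)
    return LabelVolume(grid=grid, spacing=p.spacing, case_id=p.case_id, affine=p.affine)


def check_same_grid(a: LabelVolume | ProbabilityVolume, b: LabelVolume | ProbabilityVolume) -> None:
    """Raise :class:`GridMismatchError` unless both volumes share one grid."""
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=SPACING_RTOL, atol=0.0):
        raise GridMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
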