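"""Synthetic tumor phantoms: ground-truth masks, degraded predictions and
whole cohorts with known construction parameters.

Ground truths are unions of randomly placed and oriented ellipsoidal foci,
pairwise separated by at least two voxels so that the number of foci is known
exactly.  Default focus volumes are drawn log-uniformly between 0.5 and 8 ml
— the central range of clinical single-focus tumor volumes, which span
roughly 0.01 to 500 ml across tumor types; the full range is reachable
through :class:`PhantomSpec`.

Predictions degrade the ground truth through interpretable, parameterized
error modes: per-focus misses (satellite drop-out), morphological erosion or
dilation (under-/over-segmentation of the boundary), exact volume rescaling,
rigid translation (mislocalization) and spurious disjoint false-positive
blobs.  A probability map is derived from the perturbed mask by a linear
distance ramp, ``p = max(0, 1 - d / ramp)`` with ``d`` the Euclidean distance
(mm) to the mask — chosen over smoothing because thresholding at 1.0 recovers
the perturbed binary mask *exactly*, closing the loop on the threshold-sweep
machinery.

All randomness flows from a single integer seed through per-case substreams
(``default_rng([seed, case_index, step])``), so cohorts are fully
reproducible and cases are mutually independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes_io import LabelVolume, ProbabilityVolume, write_label_volume, write_probability_volume

__all__ = [
    "PhantomSpec",
    "make_ground_truth",
    "perturb_to_prediction",
    "make_probability_map",
    "scale_mask_volume",
    "make_cohort",
    "make_dice_spread_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters for one synthetic GT/prediction pair.

    Perturbation fields all default to "no error"; a spec with the defaults
    yields a perfect prediction.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_foci: int = 1
    focus_volume_range_ml: tuple[float, float] = (0.5, 8.0)
    erode_iters: int = 0
    dilate_iters: int = 0
    translate_voxels: tuple[int, int, int] = (0, 0, 0)
    n_fp_blobs: int = 0
    fp_blob_voxels: int = 60
    drop_focus_prob: float = 0.0
    volume_scale: float = 1.0
    prob_ramp_mm: float = 4.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


_FACE = ndimage.generate_binary_structure(3, 1)
_MIN_SEPARATION_VOXELS = 2
_PLACEMENT_RETRIES = 200


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def _rasterize_ellipsoid(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
    rotation: np.ndarray,
) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the ellipsoid."""
    spacing = np.asarray(spacing, dtype=float)
    r_max = semi_axes_mm.max()
    lo = np.maximum(np.floor((center_mm - r_max) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + r_max) / spacing).astype(int) + 1, shape)
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    axes = [np.arange(lo[k], hi[k]) * spacing[k] - center_mm[k] for k in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1) @ rotation  # into ellipsoid frame
    quad = np.sum((pts / semi_axes_mm) ** 2, axis=-1)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = quad <= 1.0
    return mask


def _sample_focus_mask(
    spec: PhantomSpec,
    volume_ml: float,
    rng: np.random.Generator,
    forbidden: np.ndarray,
) -> np.ndarray:
    """Place one ellipsoidal focus avoiding the forbidden region."""
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent_mm = shape * spacing
    target_mm3 = 1000.0 * volume_ml
    for _ in range(_PLACEMENT_RETRIES):
        ratios = rng.uniform(0.7, 1.3, size=2)
        base = (3.0 * target_mm3 / (4.0 * math.pi * ratios.prod())) ** (1.0 / 3.0)
        semi = np.array([base, base * ratios[0], base * ratios[1]])
        rotation = _random_rotation(rng)
        margin = semi.max() + _MIN_SEPARATION_VOXELS * spacing.max()
        if np.any(2 * margin >= extent_mm):
            raise ValueError(
                f"a {volume_ml:g} ml focus does not fit in a grid of extent {extent_mm} mm"
            )
        center = rng.uniform(margin, extent_mm - margin)
        candidate = _rasterize_ellipsoid(spec.shape, spec.spacing, center, semi, rotation)
        if candidate.any() and not (candidate & forbidden).any():
            return candidate
    raise RuntimeError(
        f"could not place a {volume_ml:g} ml focus after {_PLACEMENT_RETRIES} attempts"
    )


def make_ground_truth(spec: PhantomSpec, rng: np.random.Generator | None = None) -> LabelVolume:
    """Union of ``n_foci`` random ellipsoids, pairwise >= 2 voxels apart.

    Focus volumes are drawn log-uniformly from ``focus_volume_range_ml``.
    Deterministic for a given spec (or supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 0])
    lo, hi = spec.focus_volume_range_ml
    mask = np.zeros(spec.shape, dtype=bool)
    forbidden = np.zeros(spec.shape, dtype=bool)
    for _ in range(spec.n_foci):
        volume = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        focus = _sample_focus_mask(spec, volume, rng, forbidden)
        mask |= focus
        forbidden |= ndimage.binary_dilation(
            focus, structure=_FACE, iterations=_MIN_SEPARATION_VOXELS
        )
    return LabelVolume(grid=mask.astype(np.uint8), spacing=spec.spacing)


def scale_mask_volume(
    mask: np.ndarray, spacing: tuple[float, float, float], scale: float
) -> np.ndarray:
    """Rescale a mask's voxel count by ``scale`` with distance-ordered growth.

    Shrinking keeps the voxels deepest inside the mask; growing annexes the
    nearest background voxels — an isotropic in-/deflation whose resulting
    count is exactly ``round(scale * count)``.
    """
    if scale <= 0:
        raise ValueError("volume scale must be positive")
    mask = mask.astype(bool)
    count = int(mask.sum())
    target = int(round(scale * count))
    if target == count or count == 0:
        return mask.copy()
    out = np.zeros_like(mask)
    if target < count:
        depth = ndimage.distance_transform_edt(mask, sampling=spacing)
        inside = np.argwhere(mask)
        order = np.argsort(depth[mask], kind="stable")[::-1]
        keep = inside[order[:target]]
        out[tuple(keep.T)] = True
    else:
        dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
        outside = np.argwhere(~mask)
        order = np.argsort(dist[~mask], kind="stable")
        add = outside[order[: target - count]]
        out[:] = mask
        out[tuple(add.T)] = True
    return out


def _translate(mask: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for axis, s in enumerate(shift):
        n = mask.shape[axis]
        if abs(s) >= n:
            return out
        src.append(slice(max(0, -s), n - max(0, s)))
        dst.append(slice(max(0, s), n + min(0, s)))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _exact_blob(
    shape: tuple[int, int, int],
    center: np.ndarray,
    n_voxels: int,
) -> np.ndarray:
    """Ball-shaped connected blob of exactly ``n_voxels`` voxels (voxel units)."""
    r = max((3.0 * n_voxels / (4.0 * math.pi)) ** (1.0 / 3.0) + 2.0, 2.0)
    lo = np.maximum(np.floor(center - r).astype(int), 0)
    hi = np.minimum(np.ceil(center + r).astype(int) + 1, shape)
    axes = [np.arange(lo[k], hi[k]) - center[k] for k in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    dist = np.sqrt(xx**2 + yy**2 + zz**2)
    flat = np.argsort(dist, axis=None, kind="stable")[:n_voxels]
    local = np.zeros(dist.shape, dtype=bool)
    local.flat[flat] = True
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = local
    return mask


def make_probability_map(
    mask: LabelVolume, prob_ramp_mm: float = 4.0
) -> ProbabilityVolume:
    """Distance-ramp probability map: 1 on the mask, decaying linearly to 0
    at ``prob_ramp_mm`` mm outside it.  Thresholding at 1.0 returns the mask
    exactly."""
    if prob_ramp_mm <= 0:
        raise ValueError("prob_ramp_mm must be positive")
    inside = mask.grid.astype(bool)
    if inside.any():
        d = ndimage.distance_transform_edt(~inside, sampling=mask.spacing)
    else:
        d = np.full(mask.shape, np.inf)
    grid = np.clip(1.0 - d / prob_ramp_mm, 0.0, 1.0)
    return ProbabilityVolume(
        grid=grid, spacing=mask.spacing, case_id=mask.case_id, affine=mask.affine
    )


def perturb_to_prediction(
    gt: LabelVolume,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> tuple[LabelVolume, ProbabilityVolume]:
    """Degrade a ground truth into a (binary mask, probability map) pair.

    Order of operations: per-focus drop-out, erosion then dilation, exact
    volume rescaling, rigid translation, then addition of false-positive
    blobs disjoint from the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 1])
    mask = gt.grid.astype(bool)

    if spec.drop_focus_prob > 0:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        for cid in range(1, n + 1):
            if rng.uniform() < spec.drop_focus_prob:
                mask[labels == cid] = False

    if spec.erode_iters > 0 and mask.any():
        mask = ndimage.binary_erosion(mask, structure=_FACE, iterations=spec.erode_iters)
    if spec.dilate_iters > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=_FACE, iterations=spec.dilate_iters)
    if spec.volume_scale != 1.0 and mask.any():
        mask = scale_mask_volume(mask, gt.spacing, spec.volume_scale)
    if any(spec.translate_voxels):
        mask = _translate(mask, spec.translate_voxels)

    if spec.n_fp_blobs > 0:
        keep_out = ndimage.binary_dilation(
            gt.grid.astype(bool), structure=_FACE, iterations=_MIN_SEPARATION_VOXELS
        )
        shape = np.asarray(gt.shape)
        for _ in range(spec.n_fp_blobs):
            for _attempt in range(_PLACEMENT_RETRIES):
                center = rng.uniform(2.0, shape - 2.0)
                blob = _exact_blob(gt.shape, center, spec.fp_blob_voxels)
                if blob.sum() == spec.fp_blob_voxels and not (blob & (keep_out | mask)).any():
                    mask |= blob
                    break
            else:
                raise RuntimeError("could not place a false-positive blob")

    pred = LabelVolume(grid=mask.astype(np.uint8), spacing=gt.spacing, case_id=gt.case_id)
    prob = make_probability_map(pred, spec.prob_ramp_mm)
    return pred, prob


def make_cohort(
    spec: PhantomSpec,
    n_cases: int,
    n_folds: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write an n-case GT/probability-map cohort plus manifest CSV.

    Folds are assigned round-robin (case i -> fold i mod n_folds).  Each
    case draws its own substreams from the spec seed, so the cohort is
    byte-reproducible; per-case construction parameters are logged to
    ``phantom_params.json`` for parameter-recovery checks.
    """
    if n_cases < n_folds:
        raise ValueError("need at least one case per fold")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    params = {}
    for i in range(n_cases):
        case_id = f"phantom_{i:04d}"
        gt = make_ground_truth(spec, rng=np.random.default_rng([spec.seed, i, 0]))
        gt.case_id = case_id
        _, prob = perturb_to_prediction(gt, spec, rng=np.random.default_rng([spec.seed, i, 1]))
        gt_path = out / f"{case_id}_gt.nii.gz"
        pred_path = out / f"{case_id}_pred.nii.gz"
        write_label_volume(gt, gt_path)
        write_probability_volume(prob, pred_path)
        rows.append(
            {
                "case_id": case_id,
                "gt_path": str(gt_path),
                "pred_path": str(pred_path),
                "fold_id": i % n_folds,
            }
        )
        params[case_id] = {"gt_volume_ml": gt.volume_ml, **spec.to_dict()}
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "phantom_params.json", "w") as fh:
        json.dump(params, fh, indent=2)
    return manifest


def make_dice_spread_cohort(
    n_cases: int,
    seed: int,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    focus_volume_range_ml: tuple[float, float] = (0.3, 10.0),
) -> list[tuple[LabelVolume, LabelVolume]]:
    """In-memory cohort whose whole-tumor Dice spans roughly 0 to 1.

    Each case is a single ellipsoidal focus whose prediction is the ground
    truth translated by a random fraction (0 to ~1.1 tumor diameters) of its
    equivalent radius, optionally lightly eroded — so mislocalization drives
    Dice continuously from perfect overlap down to disjoint masks while every
    prediction stays nonempty (surface distances remain defined).  Intended
    for metric-correlation studies.
    """
    cohort = []
    for i in range(n_cases):
        spec = PhantomSpec(
            shape=shape,
            spacing=spacing,
            n_foci=1,
            focus_volume_range_ml=focus_volume_range_ml,
            seed=seed,
        )
        rng = np.random.default_rng([seed, i])
        gt = make_ground_truth(spec, rng=rng)
        gt.case_id = f"spread_{i:04d}"
        # equivalent sphere radius in voxels (isotropic spacing assumed here)
        r_eq = (3.0 * gt.foreground_count / (4.0 * math.pi)) ** (1.0 / 3.0)
        severity = rng.uniform(0.0, 1.0)
        distance = severity * 2.2 * r_eq
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # clamp the shift so the translated tumor stays inside the grid
        # (keeps the prediction nonempty, hence surface distances defined)
        idx = np.argwhere(gt.grid)
        lo, hi = idx.min(axis=0), idx.max(axis=0)
        shift = tuple(
            int(np.clip(round(distance * d), -lo[k], shape[k] - 1 - hi[k]))
            for k, d in enumerate(direction)
        )
        erode = int(rng.integers(0, 2))
        pert = PhantomSpec(
            shape=shape,
            spacing=spacing,
            erode_iters=erode,
            translate_voxels=shift,
            seed=seed,
        )
        pred, _ = perturb_to_prediction(gt, pert, rng=rng)
        if pred.foreground_count == 0:  # erosion killed a tiny focus
            pred = LabelVolume(grid=_translate(gt.grid.astype(bool), shift).astype(np.uint8),
                               spacing=spacing, case_id=gt.case_id)
        pred.case_id = gt.case_id
        cohort.append((gt, pred))
    return cohort
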