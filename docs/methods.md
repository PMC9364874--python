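# Methods

This note documents the measurement conventions, the synthetic data model,
and the design choices made where published practice is ambiguous.

## Scope and data model

The unit of comparison is a pair of 3-D volumes on an identical grid: a
binary ground-truth mask and either a binary predicted mask or a probability
map in [0, 1], with voxel spacing in mm taken from the NIfTI header. The
package performs no resampling or registration; masks are assumed to be
produced on (or resampled to) a common grid upstream, and report features
that need a reference space (laterality, atlas location profiles) assume the
input was already aligned to a symmetric atlas such as MNI ICBM2009a.
Multi-label inputs collapse to a single foreground class: the whole tumor
extent is evaluated as one entity.

## Voxel-wise metrics

Everything except the spatial distances is an exact function of the
confusion counts (TP, FP, TN, FN), computed in a single pass. A generic
per-voxel/partition oracle (explicit region sets for GCE, scikit-learn's
clustering scores for κ/ARI/NMI, the Pearson correlation of flattened grids
for MCC) exists only in the test suite, as an independent cross-check.

Conventions that needed fixing because usage differs across toolkits:

- **NMI** normalizes mutual information by the *arithmetic mean* of the two
  marginal entropies; **VOI** is reported in nats. NMI is undefined for a
  constant mask (zero entropy).
- **RAVD** is the *signed* relative difference with the GT volume as
  reference. Despite the word "absolute" in its conventional name, its
  stated range [−1, ∞) is only attainable by a signed quantity.
- **GCE** is stored as a raw fraction; tabular reporting conventionally
  scales it by 1e4.
- **AUC** of a hard binary prediction is (TPR + TNR)/2 — the trapezoidal
  area under the single-operating-point ROC.
- **ARI** uses the pair-counting formula on the 2×2 contingency table, with
  exact integer arithmetic (pair counts overflow 64-bit floats on large
  grids). When the normalizer degenerates (both partitions constant) the
  value is 1.0, matching the common clustering-library convention.
- **PBD** is Σ|g−p| / (2Σgp); it accepts a fuzzy prediction but by default
  is computed on the same binarized mask as every other metric, since the
  panel is defined on the thresholded map. Zero overlap gives +inf, treated
  as undefined for pooling.
- **Undefined values are flagged, never coerced to 0.** A vanishing
  denominator (PPV of an empty prediction, RAVD of an empty GT) yields NaN
  and the case is simply absent from that metric's aggregates. This mirrors
  the Dice-TP idea: eligibility, not zero-filling.

## Surface distances

Borders are face-adjacency (6-neighborhood) border voxels, including voxels
at the grid edge; border-voxel centers are scaled to mm by the anisotropic
spacing. Nearest distances are exact (KD-tree; validated against an O(n²)
scan at 1e-6 mm).

- **HD95** is the 95th percentile — linear interpolation between order
  statistics — of the *pooled* bidirectional distance multiset, not the max
  of per-direction percentiles. Pooling is stated explicitly because both
  conventions circulate.
- **ASSD** is the mean of the same pooled multiset. The pooled mean can
  exceed HD95 when a small (<5 % of border points), far-away false-positive
  component dominates the tail.
- **Mahalanobis distance** is √(Δᵀ S⁻¹ Δ) for the centroid difference Δ
  under the size-weighted pooled covariance S = (n₁S₁ + n₂S₂)/(n₁+n₂) of
  the two border point sets (biased per-set covariances). S is regularized
  with +1e-6 mm² on the diagonal so single-voxel, sheet-like or collinear
  surfaces remain invertible; published variants differ in the covariance
  weighting, so this is a declared choice.
- An empty mask has no surface: all distance metrics for that case are
  undefined and excluded from distance pooling.

## Instance analysis

Connected components use 26-connectivity by default (6/18 configurable);
components below 50 voxels are discarded from *both* GT and prediction —
symmetric filtering avoids counting sub-resolution specks as either targets
or false alarms. Each predicted component is assigned to the GT component
maximizing their pairwise Dice (ties: larger GT component, then lower id —
making the pairing invariant to enumeration order), and kept when that Dice
is strictly greater than the detection threshold (default 0; a small
positive threshold such as 0.001 is configurable, since both conventions
appear in practice — the difference only matters for single-voxel grazes).
Matching is many-to-one: a fragmented but correct prediction does not
inflate FPPP, while each predicted object is counted exactly once.

Patient-wise recall counts a patient as detected when the whole-tumor Dice
exceeds the detection threshold. Patient-wise precision counts against it
the patients with at least one predicted object but no detection (a
spurious-only prediction) — an operational reconstruction, since cohorts
without tumor-free patients leave the definition under-determined. OASSD is
the mean pairwise ASSD over matched object pairs, undefined with no match.

## Cohort reporting

Probability maps are swept over the ten thresholds {0.1, …, 1.0} with the
rule "foreground iff p ≥ t"; t = 0 is excluded because it would mark every
voxel foreground. The operating threshold, when one must be chosen, is the
PT maximizing mean validation-fold Dice (ties to the lower PT) — a
declared rule, as published studies rarely state theirs.

Pooled estimates use the case-weighted mean and the variance decomposition
given in the README; the formulas reproduce the mean/SD of the concatenated
cohort exactly for any fold sizes (a property the test suite asserts at
1e-9). Note that with identical fold means the pooled SD is
√(Σ(nᵢ−1)sᵢ²/(Σnᵢ−1)), slightly below the common fold SD — the
concatenated-sample value, which we take as the definition.

The metric correlation matrix is pairwise-complete Pearson over per-case
values, rounded to two decimals for presentation (raw values available);
cases with an undefined value are dropped per entry, not cohort-wide.
FPR/FNR are excluded as exact complements of TNR/TPR, and cohort-level
detection rates are excluded because they are not per-case quantities.
Volume-binned Dice summaries use equal-*count* (decile) bins ordered by GT
volume (ties by case id), reporting quartiles and 1.5×IQR outlier counts
per bin.

## Synthetic phantoms

The generator emulates the relevant statistics of clinical tumor cohorts,
not their appearance: single- or multifocal masks with focus volumes drawn
log-uniformly (defaults 0.5–8 ml; clinical whole-cohort ranges run from
about 0.01 to several hundred ml and are reachable through the spec),
anisotropic spacing, and degraded predictions spanning Dice 0–1. Foci are
random-orientation ellipsoids with axis ratios in [0.7, 1.3], placed with
at least two voxels of separation so instance counts are known by
construction.

Degradations are parameterized and individually recoverable: per-focus
drop-out (satellite misses), 6-neighborhood erosion/dilation, exact volume
rescaling (distance-ordered voxel addition/removal, hitting
round(s·V) voxels exactly, so RAVD recovers s−1), rigid translation, and
disjoint false-positive blobs of an exact voxel count. The probability map
is a linear distance ramp p = max(0, 1 − d/ramp) from the perturbed mask
(default ramp 4 mm): unlike Gaussian smoothing, thresholding at 1.0 returns
the perturbed binary mask *exactly*, which closes the loop on the
threshold-sweep machinery. All randomness derives from one integer seed via
per-case substreams, so cohorts are byte-reproducible and cases
independent.

What the phantoms do **not** model: MRI intensities, texture, bias fields,
infiltrative/diffuse boundaries, rater variability, or anatomically
plausible lesion placement. Passing tests therefore certify the *metric
machinery* — definitions, degenerate-case handling, aggregation — on masks
with controlled error structure; they say nothing about how any particular
segmentation model performs on real data.

## Problem sizes and numerics

Default test/benchmark grids are 32³–64³ voxels at 1 mm isotropic — large
enough for stable surfaces and component structure while keeping the full
suite and the acceptance analysis in the tens of seconds. The correlation
analysis uses 300 cases at 64³ (foreground fraction ≤ ~4 %, matching the
small tumor-to-brain volume ratio that makes κ/ARI numerically close to
Dice in practice). Spacing comparisons use 1e-4 relative tolerance;
probability inputs are clipped to [0, 1] within 1e-6; the covariance
regularizer is 1e-6 mm². Percentiles interpolate linearly. Integer pair
counts in the ARI use exact Python integers.

## Known limitations

- Binary (whole-tumor) evaluation only; no per-label multi-class panel.
- No mesh-based surfaces or exact (100th-percentile) Hausdorff reporting.
- The Mahalanobis covariance weighting is one of several published variants.
- Patient-wise precision relies on the reconstruction described above.
- Registration, skull-stripping and DICOM ingestion are out of scope.
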