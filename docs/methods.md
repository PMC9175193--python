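# Methods

This note documents the models, conventions and design choices behind
`cstmotor`, in the order the pipeline runs.

## Tractometry

**Resampling.** Each streamline (a 3D polyline in mm) is resampled to 100
points at equal arc-length spacing by linear interpolation along the
polyline; the endpoints are preserved exactly.  The along-tract convention
is segment 0 at the medulla oblongata (inferior) and segment 99 at M1
(superior); 100 points define the 100 segments of a profile.
`orient_streamlines` enforces the convention by reversing any streamline
whose first point lies closer to the superior anchor than its last point
(idempotent).

**Scalar sampling.** Metric maps are sampled trilinearly at the resampled
points after mapping mm coordinates through the inverse of the map's
affine.  Points outside the grid become *missing* (NaN), never zero —
zeros would drag profiles toward the background value.

**Profile estimators.** Two per-segment summaries across streamlines:

* *median* — robust to outlier streamlines by construction;
* *weighted mean* — each streamline's point is weighted by the inverse of
  its Mahalanobis distance from the tract core.  The core is the mean
  point of the segment and the covariance is the per-segment 3×3 sample
  covariance across streamlines.  Because no degenerate-case rule is
  standard, the covariance is regularised by `eps = 1e-6·trace/3 + 1e-12`
  on the diagonal and distances are floored at `1e-8` before inversion;
  this makes a bundle of identical streamlines return the common values
  instead of 0/0.  Per-segment (not pooled) covariance was chosen because
  bundle cross-sections change shape along the tract.  Missing samples are
  excluded with weight renormalisation; a segment with no valid sample is
  missing.  The weighted mean is a convex combination, so it always lies
  within the per-segment value range.

## Tensor estimation

The log-linear signal model `ln S = ln S0 − b gᵀDg` is solved per voxel
for the six tensor elements plus `ln S0`.  `n_iter` counts weighted
solves: the first uses weights from the OLS-predicted signals, later ones
re-derive weights from the current model prediction; weights are the
squared predicted signals.  `n_iter = 0` is therefore exactly ordinary
log-linear least squares, and the default `n_iter = 2` gives the usual
two-pass iteratively reweighted estimator.  The precise IRLLS variant
(weight formula, iteration count) is not pinned down by name alone, so
these choices are stated here and tested.

Eigenvalues are sorted descending and clamped at zero before scalar
computation (negative eigenvalues from noisy fits are a known artefact;
clamping is standard practice).  FA is defined as 0 where all eigenvalues
vanish.  Voxels with any non-positive signal are excluded via the fit
mask.  FD is never computed from DWI — single-shell acquisitions are
poorly suited to fibre-density estimation, so FD enters the pipeline only
as a precomputed (here synthetic) map.

The deterministic 40-direction, b = 1000 s/mm² scheme is generated by the
golden-spiral construction, which distributes directions approximately
uniformly over the sphere.

## Synthetic cohort generator

The generator emulates the study conditions the analysis was designed
for; it is the test bed for every downstream stage, not a model of real
anatomy.

* **Cohort structure.** 116 patients by default at 45/116 deficit
  prevalence.  Labels are assigned by exact counts
  (`round(n·prevalence)`), shuffled deterministically — this keeps the
  statistical power of planted-effect experiments well defined.  Ages are
  drawn per class from N(50.25, 15.85²) / N(58.64, 15.45²) years;
  gender, WHO grade, tumour location, lesion side and resting motor
  thresholds follow the per-class frequencies of the emulated cohort
  design.  MRC score is 5 for class 0 and uniform on 1–4 for class 1;
  class 1 iff MRC < 5.
* **Bundles.** 5000 streamlines per hemisphere by default, each the
  smooth CST-like centerline displaced by a constant random offset in the
  local perpendicular plane (isotropic Gaussian, SD = `bundle_radius_mm`
  per axis).  The pointwise mean of the bundle therefore concentrates on
  the centerline at the CLT rate, which the tests exploit.
* **Metric fields.** Per (patient, hemisphere, metric):
  `baseline(segment) + patient offset + lesion shift · 1[window] + voxel noise`.
  Baselines are physiological tract values (FA 0.55, FD 0.45,
  AD 1.4·10⁻³, RD 0.45·10⁻³, ADC 0.77·10⁻³ mm²/s) with a gentle 5%
  sinusoidal along-tract variation so profiles are not flat.  The patient
  offset ~ N(0, `noise_sd_per_metric`) is the *between-patient*
  variability and dominates the segment-level SD; voxel noise is half
  that SD because averaging over thousands of streamlines suppresses it.
  `effect_size` is therefore interpretable as the planted between-class
  shift in units of the within-class SD.  The shift applies only to
  deficit-class patients, only on the ipsilesional side, only inside the
  lesion window (default segments 78–98, the superior tract portion), and
  with the pathological sign per metric (FA/FD down, AD/ADC/RD up).
  Lesion boundaries are hard in the field; trilinear interpolation blurs
  roughly one segment on either side, which planted-shift recovery tests
  account for.
* **Missingness** is uniform at random over segments (default 2%),
  applied identically to both profile estimators.
* **Seeding.** A single global seed fans out as
  `SeedSequence((seed, patient_index, stream))`, where `stream`
  enumerates the independent draws (attributes, left/right bundle,
  left/right fields, missingness), so any patient regenerates in
  isolation and cohorts are byte-reproducible.
* **DWI phantoms** use the closed-form single-tensor signal with Rician
  noise (magnitude of a complex Gaussian perturbation), the appropriate
  model for magnitude MR data.

What the generator does **not** emulate: tumour mass effect and
deformation, realistic anatomy or atlases, fibre crossings, FOD/CSD
simulation, spatially correlated noise, scanner artefacts.  Passing tests
therefore demonstrate the correctness and statistical behaviour of the
pipeline under its own assumptions — not clinical performance on real
data, whose headline numbers depend on a non-public cohort.

## Feature engineering

Histogram features per profile: M (mean), STD (sample SD, n−1),
SK = m₃/m₂^1.5 and KU = m₄/m₂² − 3 with population central moments —
the conventions of the common scientific Python stack (`scipy.stats.skew`
/ `kurtosis` with `bias=True`), asserted by a cross-check test.
Zero-variance profiles get SK = KU = 0; at least 4 valid segments are
required.  Hemispheres are relabelled ipsi/contra per patient before
assembly; 40 (histogram) or 1000 (segment) imaging columns result, plus
an optional clinical block (age, gender 0/1, ordinal WHO grade, one-hot
location, ipsi/contra RMT — encodings chosen for linear-model
compatibility).

Imputation operates on the assembled feature table: `median` fills with
train-column medians; `knn` (k = 10) fills each incomplete row from the
mean of its k nearest training rows, with Euclidean distance over the
columns observed in both rows and stable tie-breaking by row order.  This
differs from per-column KNN imputers and is therefore implemented
directly and verified against a brute-force oracle.  Since histogram
features already skip missing segments, imputation is mostly active in
segment mode.  Standardisation is the z-score with train mean/SD
(zero-variance columns get scale 1); PCA keeps the first 4 components
fitted on the standardised training rows.  The pipeline order —
impute → standardise → (PCA) → classify, all statistics train-only — is
enforced structurally and by leakage tests.

## Group statistics

* Segment-wise two-sample pooled-variance t-tests; missing values omitted
  per segment; BH-FDR applied across the 100 segments of one
  metric/hemisphere family (the family definition is configurable since
  no single convention is canonical).  Zero-variance-in-both-groups
  segments get p = 1 (equal means) or p = 0.
* Mann–Whitney U with the tie-corrected normal approximation; the
  reported Z omits the continuity correction so that r = |Z|/√n matches
  the standard closed form on small samples; all-equal data returns
  r = 0, p = 1.
* Categorical association branches purely on expected counts: Fisher's
  exact test when any expected cell < 5 (2×2 only), else Pearson χ² with
  Yates continuity correction for 2×2 tables — the convention that
  reproduces standard-stack defaults.
* Hedges g with the usual small-sample correction and a large-sample
  normal CI; the p-value comes from the equivalent two-sample t.
* CCA against age: with a single right-hand variable the first canonical
  correlation equals the multiple correlation of age on the feature
  block, computed from the covariance solve; rank-deficient blocks are
  ridge-regularised (λ = 1e-8) with a warning, and n ≤ p + 1 is refused —
  so the 1000-dimensional block cannot be used at cohort-sized n.

## Classifier

Class weights w_j = n/(2·n_j) keep n₀w₀ + n₁w₁ = n.  SVM-RFE drops one
feature per iteration (the smallest |coefficient| of a class-weighted
linear SVM at C = 1; ties drop the highest column index for
determinism) until `rfe_k = 5` survive — the default count matches the
size of the reported selected-feature set, and is configurable.  The
penalty grid is 0.1, 0.2, …, 10.0 (100 values; 0 is invalid for the SVM
penalty).  Inner tuning scores balanced accuracy on a stratified
5-fold CV and returns the smallest C attaining the maximum (the simplest
model wins ties).

Bagging draws stratified bootstrap resamples (per-class counts preserved,
so a resample can never lose a class — plain bootstrap could at
cohort-scale prevalence).  `n_bootstrap = 1` is defined as *no bagging*:
the single "resample" is the full training set, making the un-bagged
pipeline a special case.  Votes are combined by majority (ties to the
deficit class); the ROC score is the mean signed decision value.  AUC is
computed rank-based with ties counting one half.

`tuning_scope` resolves a genuine ambiguity in where selection/tuning
live: `"resample"` (default) runs RFE and the C grid search inside every
bootstrap resample; `"fold"` runs them once per outer fold and lets
resamples only refit the final SVM.  The fold scope is the documented
fast mode used for large simulation studies.

## Problem sizes in shipped runs

Defaults follow the emulated study (116 patients, 5000 streamlines,
1000 bootstrap resamples).  The shipped simulation studies (acceptance
tests and `scripts/acceptance.py`) use scaled problem sizes chosen as a
package decision to keep desk-scale runs short while leaving the
statistical conclusions unchanged: 200 patients, 200 streamlines per
hemisphere, 3 mm voxels for the synthetic grids, 50 bootstrap resamples,
fold-scope tuning, and 10 null-cohort seeds.  At these sizes the planted
2-SD ADC/FA effect is recovered with pooled AUC ≈ 1 and the null cohorts
give AUC ≈ 0.5; both quantities are recomputed, never stored.

## Known limitations

* The weighted-mean estimator's covariance scope (per segment) and the
  IRLLS weight scheme are reasonable conventions, not uniquely determined
  ones; both are isolated behind tested functions.
* KNN imputation is O(n²) in rows; adequate at cohort scale, not tuned
  for biobank scale.
* The synthetic lesion model is piecewise-constant in segment space;
  real lesions have graded boundaries and displace tracts.
* `segments1000+pca` at small n inherits the usual instability of
  high-dimensional PCA; it is included as a model variant, not a
  recommendation.
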