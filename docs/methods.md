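# Methods

This note records the models, conventions and numerical choices behind
`relomics`, and what the simulation-based tests do and do not
demonstrate.

## Preprocessing

Each lesion ROI is processed in a fixed order: square-root transform of
the native PET intensities (variance stabilisation for count noise;
negative reconstructed values are clipped to 0 first, since activity is
non-negative), crop to the mask bounding box with a 1-voxel pad,
isotropic resampling, then gray-level quantisation. The transform is
applied before resampling so the interpolation acts on the
noise-stabilised image; the alternative order changes features only at
the interpolation-error level.

**Resampling.** Image and mask are resampled with SimpleITK onto an
isotropic grid covering the input bounding box (default 0.97 mm,
matching a typical diagnostic CT pixel). The image uses trilinear
interpolation; the mask indicator is trilinearly interpolated and
re-binarised at 0.5. Thresholded linear interpolation was chosen over
nearest-neighbour sampling because at the ~2:1 spacing ratios involved
NN aliasing systematically sheds several percent of lesion volume,
while the 0.5-level set conserves digital-sphere volumes to well under
5 %.

**Quantisation.** Lloyd–Max scalar quantisation of the masked
intensities to `Ng = 32` levels, per lesion over that lesion's own
intensity range. Centroids initialise at the `Ng` equal-probability
quantiles; iterations alternate nearest-centroid assignment (midpoint
thresholds) and centroid means; convergence when the largest centroid
move is below 1e-8 × intensity range or 500 iterations; empty bins are
repaired by splitting the most populous bin. Lloyd iterations never
increase the mean squared quantisation error but converge to a local
optimum — the brute-force-optimality test therefore uses well-separated
clusters where the quantile initialisation reaches the global optimum.
Inputs with ≤ Ng distinct values are encoded losslessly; constant
inputs map to a single level.

## Feature panel

46 features per lesion: volume (mL), sphericity, 4 mean-subtracted
first-order features (population central moments: variance, CoV,
skewness, kurtosis — computed on the root-transformed, resampled
intensities, not the quantised levels), and 40 texture features.

* **GLCM (9)** and **GLRLM (13)**: the 13 unique 3-D directions at
  distance 1 are aggregated by summing count matrices before
  normalisation (merged strategy), giving one rotation-robust matrix
  per family. GLRLM run percentage is defined as runs per voxel per
  direction so it stays in (0, 1] under the merged convention.
* **GLSZM (13)** and **NGTDM (5)**: 26-connectivity, mask-restricted
  neighbourhoods.
* Degenerate conventions: GLCM correlation = 0 when a marginal is
  constant; NGTDM coarseness capped at 1e6 for homogeneous ROIs;
  busyness/complexity/strength are 0 when only one level is present.

**Sphericity** is π^{1/3}(6V)^{2/3}/A with V the voxel-count volume and
A a surface-area estimate obtained by summing boundary voxel faces
weighted by |n̂·ê|, where n̂ is the local surface normal estimated from
the gradient of a Gaussian-smoothed mask (σ = 1.5 voxels). By the
projection relation between a staircase surface and its underlying
plane this is exact for axis-aligned boxes (a 1 mm cube scores exactly
6 mm², sphericity 0.806) and accurate to ~1 % for digital spheres;
plain marching cubes bevels small boxes (octahedron artefact) and
supersampled marching cubes inherits the ~50 % staircase overestimate
on spheres. Known limitation: small multi-voxel boxes (2–4 voxels per
edge) have their edge-face normals smeared, underestimating A by up to
~20 %; lesion masks are blob-like, where the estimator is accurate.

## Phantom simulator

The robustness phantom is a digital stand-in for a liver/lung torso
phantom: an ellipsoidal warm liver compartment (semi-axes 90 × 62 ×
52 mm, ~1.2 L) holding a 29-mL ellipsoid and 16-mL and 8-mL spheres at
6.0 vs 1.2 MBq/mL (5:1 contrast), on a 2-mm grid. Reconstruction is
*not* simulated: the OS-EM iteration setting is surrogated by the
acquisition noise level (σ-fraction 0.15 for the 1-iteration surrogate,
0.25 for 2 iterations — more updates amplify noise in OS-EM) and the
post-filter setting by a Gaussian PSF of 0 or 5 mm FWHM applied to the
noiseless concentration map, giving 2 × 2 conditions × 5 repeats.
Noise is Gaussian with σ = frac × (ground truth + floor), floor = 5 %
of the background concentration, clipped at 0 — a pragmatic model of
very-low-count ⁹⁰Y PET without Poisson/sinogram machinery. Insert
masks are voxelised once (volume must match nominal within 5 %) and
shared bit-identically across acquisitions, which is what makes the
sphericity CCC exactly 1.

What this does and does not show: the simulated robust set reproduces
the *qualitative* structure expected of real phantom data (shape
features perfectly robust; gray-level/zone nonuniformity and NGTDM
features robust; absolute-intensity-coupled features fragile), but the
exact membership of the robust set depends on scanner noise texture
that a Gaussian surrogate cannot capture, so no claim is made that the
simulated screen returns the same 15 features a physical phantom study
yields.

## Cohort generator

Features (ZP, ZSN, dose + 12 nuisance texture surrogates) are drawn
from a multivariate normal on the standardized scale; printed
lesion-level correlations are used where available (ZP–dose 0.483,
ZSN–dose −0.057), ZP–ZSN is set to 0.30 (not reported; texture panels
are generally intercorrelated while ZSN is nearly dose-independent),
and nuisance features get exchangeable 0.5 correlation with 0.3/0.2
loading on the texture/dose axes. Outcomes follow the reported models:
OR ~ Bernoulli(expit(−0.892 + 0.520 ZP + 0.488 dose)); progression time
is exponential with rate h₀·exp(−0.530 ZSN − 1.707 dose) and
independent exponential censoring. The baseline hazard (2.4e-4/day) and
censor rate (1/300/day) were calibrated once against the printed cohort
facts (≈14 % progression events, median observed time ≈170–230 days)
and frozen. A display dose is emitted as 265·exp(0.7·Z) Gy (median
265 Gy, mean ≈340, range spanning ~1–1300 Gy). Subgroups default to
35:70 HCC:metastasis with no subgroup effect. All randomness flows from
a single `SeedSequence`.

The generator emulates the *statistical* structure of a lesion cohort,
not the imaging chain: features are drawn on the standardized scale
rather than extracted from images, there are no repeated measures
within patients (each lesion is independent), and censoring is
independent of the features. Tests that pass on these cohorts show the
modelling machinery is correct and calibrated, not that real ⁹⁰Y
cohorts satisfy the generating assumptions.

## Modelling framework

* Features are z-scored with training-split statistics before any
  penalised or unpenalised fit (L1 requires comparable scales, and the
  printed coefficient magnitudes are only plausible for standardized
  inputs).
* λ grid: `n_lambda` geometric points from λ_max (smallest penalty
  zeroing all coefficients) down three decades; inner tuning is
  stratified K-fold CV minimising validation deviance (log loss for
  logistic, Breslow negative log partial likelihood for Cox).
  Logistic L1 paths use liblinear; Cox L1 paths use coxnet
  (scikit-survival).
* Bootstrap resamples are stratified by outcome (response flag or
  event flag); degenerate resamples are redrawn up to 20 times.
  Ranking ties break by mean absolute bootstrap coefficient, then
  feature name — fully deterministic.
* Model order: the same M resamples are reused for every order so the
  order comparison is paired, which stabilises the one-SE rule; the SE
  is the standard error of the best order's out-of-bag metric mean.
  The chosen order is the smallest within one SE of the best.
* Outer loop: repeated stratified K-fold (default 10×5). All
  selection, tuning and standardization happen inside each training
  split; each fold's pipeline is seeded by a fold-specific
  `SeedSequence` child so the trained fold model is a pure function of
  (training rows, fold seed) — the leakage test verifies this bitwise.
  Fold metrics: AUC or Harrell's c-index (comparable pairs, 0.5 credit
  for prediction ties); the CI is a 1000-resample percentile bootstrap
  over the fold metrics.
* The reported final model is rank + order-select + refit on the full
  dataset; its generalisation estimate comes only from the nested CV.
* Cox ties: Breslow (statsmodels PHReg); the baseline cumulative
  hazard is the Breslow estimator. Monotone-likelihood fits are capped
  at |β| = 10 with a warning.
* ADASYN is applied inside training folds only, balancing the minority
  class to the majority count with density-weighted interpolation
  between minority neighbours (k = 5); for progression the survival
  times are interpolated with the same weights. It is refused when the
  minority count is ≤ k (the reason it is inappropriate for a 4-event
  subgroup).
* Calibration and KM stratification use pooled out-of-fold
  predictions (mean per lesion across CV repeats) when a nested CV was
  run — in-sample recalibration of an MLE logistic fit is trivially
  (1, 0) and only useful as a smoke check.

### Null behaviour

Under label permutation a selection pipeline at n ≈ 100 is slightly
*anti*-predictive on held-out folds: selecting the feature most
correlated with training noise forces the held-out part of a finite
permutation toward the opposite correlation. Single permutations also
carry realised correlations of either sign. The chance-level test
therefore averages the 50-fold nested-CV mean over three permutations,
which lands in the 0.45–0.55 band.

## Problem sizes

Library defaults are the study conditions (N = M = 100 bootstraps,
10×5-fold outer CV, 50-point λ grid, inner 5-fold). The test and
acceptance suites scale the bootstrap counts to 5–25 and the λ grid to
8–15 points with inner 3-fold CV, and run the phantom feature
extraction at 2 mm isotropic sampling — sizes chosen so the full
simulation studies remain quick to iterate while leaving every
qualitative conclusion (rankings, chosen orders, robustness flags,
null behaviour) unchanged.

## Known limitations

* No PET reconstruction, partial-volume or registration modelling; the
  robustness screen characterises the surrogate noise model only.
* The sphericity area estimator under-measures sharp multi-voxel
  rectilinear corners (see above).
* Lloyd–Max finds local optima for pathological intensity histograms.
* Cohorts treat lesions as independent; the clustered (per-patient)
  structure of real radioembolization cohorts is not simulated.
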