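# relomics

Lesion-level radiomics and absorbed-dose outcome modelling for ⁹⁰Y
radioembolization PET.

After transarterial radioembolization of liver tumours with ⁹⁰Y
microspheres, the post-therapy PET scan carries two kinds of predictive
information per lesion: the mean absorbed dose (Gy) and the spatial
texture of the activity distribution. `relomics` implements the full
analysis chain needed to combine them into lesion outcome models, for
imaging physicists and outcome-modelling researchers:

1. **Preprocessing** — square-root intensity transform, isotropic
   resampling (0.97 mm default), and Lloyd–Max minimum-MSE quantisation
   of each lesion ROI to `Ng = 32` gray levels.
2. **Feature extraction** — a 46-feature panel per lesion: volume,
   sphericity, 4 mean-subtracted first-order features, and 40 texture
   features from the 3-D GLCM (9), GLRLM (13), GLSZM (13) and NGTDM (5)
   matrix families (13-direction merged aggregation, 26-connectivity).
3. **Robustness screening** — because ⁹⁰Y PET is extremely noisy, a
   simulated liver phantom (29-mL ellipsoid + 16-mL and 8-mL spheres at
   5:1 insert:liver activity, five repeated acquisitions under four
   reconstruction-surrogate conditions) is used to keep only features
   whose mean Lin concordance correlation coefficient across
   acquisition pairs exceeds 0.85:

   CCC(x, y) = 2·cov(x, y) / (σ²ₓ + σ²ᵧ + (μₓ − μᵧ)²)

4. **Outcome modelling** — a bootstrap-stabilised LASSO inside nested
   cross-validation. On each training split, features are ranked by
   their selection frequency over N = 100 stratified bootstrap
   resamples (L1 penalty tuned per resample by inner CV); model order
   is chosen from M = 100 bootstrap out-of-bag metric curves with a
   one-standard-error parsimony rule; the top-k features are refit
   unpenalised (logistic for binary overall response, Cox with Breslow
   ties for time to progression); performance is the mean AUC /
   Harrell c-index over the 10×5 outer folds with a percentile
   bootstrap CI. ADASYN oversampling, Kaplan–Meier median-risk
   stratification (log-rank test) and logistic recalibration
   (slope/intercept) round out the toolkit.

A synthetic-cohort generator draws lesion tables whose outcomes follow
the reported generative structure — response from
`logit P(OR=1) = −0.892 + 0.520·ZP + 0.488·dose` and progression from
`h(t) = h₀·exp(−0.530·ZSN − 1.707·dose)` with exponential
right-censoring — so the entire pipeline is testable without any
patient data. Here ZP (zone percentage) and ZSN (zone size
nonuniformity) are GLSZM texture features and `dose` is the
standardized mean absorbed dose.

## Worked example

```python
from relomics import (CohortGenConfig, generate_cohort,
                      LesionResponseModel, ModelingConfig)

cohort = generate_cohort(CohortGenConfig(n_lesions=105, seed=1))
feats = ["ZP", "ZSN", "dose"] + [c for c in cohort.data.columns
                                 if c.startswith("tex")]
cfg = ModelingConfig(outer_repeats=10, outer_folds=5,
                     n_bootstrap_rank=15, n_bootstrap_order=15,
                     n_lambda=15, inner_folds=3, seed=1)
res = LesionResponseModel.from_dataframe(cohort.data, features=feats,
                                         config=cfg).fit()
print(res.summary())
```

prints

```
Lesion response model
=====================
endpoint: OR    n lesions: 105
model order (one-SE rule): 2 of 15 ranked features

coefficients (standardized scale)
---------------------------------
  intercept           -0.824
  ZP                   0.948   (selection freq 1.00)
  dose                 0.583   (selection freq 0.93)

nested-CV AUC
-------------
  HCC       0.677  (95% CI 0.614-0.741, 50 folds)
  all       0.728  (95% CI 0.702-0.754, 50 folds)
  met       0.760  (95% CI 0.730-0.788, 50 folds)
```

The framework recovered the two features that generated the outcomes
(ZP and dose, order 2 by the one-SE rule), and the nested-CV AUC of
0.728 estimates how well the two-feature logistic model generalises to
unseen lesions of this synthetic cohort; the subgroup rows apply each
fold's model to the HCC / metastasis members of its held-out fold.
`res.calibration()` on the same fit returns the out-of-fold
recalibration slope and intercept (here `(0.767, -0.111)` — mild
overfitting shrinkage, as expected from a selection pipeline at
n = 105).

The same API fits progression models
(`LesionProgressionModel`, c-index, `res.km_stratification()`), and a
`relomics` command-line tool exposes the pipeline stages
(`phantom`, `extract`, `robust`, `simulate-cohort`, `fit`).

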