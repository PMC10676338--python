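# Methods

## The problem

Features pooled across acquisition sites carry site-specific location and
scale distortions. Removing them ("harmonization") before a cross-validated
case/control analysis is standard practice, but the common deployment fits
the harmonizer on the *whole* dataset — including the subjects later used
as test folds — which couples every harmonized value to every subject and
quietly breaks the train/test separation. This package implements one
pinned harmonizer and four ways of placing it relative to the CV loop, plus
the two measurements that expose the consequences: how recognizable the
sites remain, and how stable classification performance and feature
rankings are across placements.

## Harmonization model

Per feature `v`, subject `j` at site `i`:

```
y_ijv = alpha_v + x_ij' beta_v + gamma_iv + delta_iv * eps_ijv,
eps_ijv ~ N(0, sigma_v^2)
```

Fitting (reference-population mode — every estimate uses only the
designated reference subjects, by default the TD controls):

1. Least squares for `alpha, beta, gamma` with the weighted constraint
   `sum_i n_i gamma_iv = 0` (one site indicator per site plus covariates;
   the grand intercept is the reference-size-weighted mean of the site
   intercepts).
2. Pooled scale `sigma_v^2` = mean squared residual of the full fit.
3. Standardization `z_ijv = (y_ijv - alpha_v - x_ij' beta_v) / sigma_v`;
   the site signal stays in `z`.
4. Raw site effects: `gamma_hat_iv = mean(z)`,
   `delta_hat_iv^2 = mean((z - gamma_hat_iv)^2)` within site (both ddof 0,
   so a single-site fit yields `gamma_hat = 0`, `delta_hat = 1` exactly and
   the transform is the identity).
5. Parametric empirical Bayes, independently per site: `gamma` prior
   `Normal(gamma_bar_i, tau_i^2)`, `delta^2` prior
   `InverseGamma(lambda_i, theta_i)`, hyperparameters moment-matched across
   features within the site; conditional posterior means iterated to a
   fixed point (max relative change `< 1e-4`, cap 100 iterations,
   non-convergence raises). If the raw estimates carry no between-feature
   spread (variance across features below 1e-12, as in a single-site or
   single-feature fit), that side of the shrinkage degenerates and the raw
   estimates are kept.

Application, to any subject whose site was in the reference:

```
y*_ijv = sigma_v * (z_ijv - gamma*_iv) / delta*_iv + alpha_v + x_ij' beta_v
```

Row-wise by construction: a subject's harmonized values depend only on its
own row and the fitted model. Unknown sites raise rather than passing data
through. Covariates are linear; age is the default; diagnosis is never a
covariate (it must be treated as unknown for test subjects). A
`empirical_bayes=False` switch exposes the raw location/scale variant,
which the tests compare against an independently coded closed-form oracle.
Structural and connectivity feature sets are harmonized independently.

## Deployment strategies

Given a CV plan (k folds × R repetitions, stratified on the joint
(class, site) label):

- `none` — fold slicing of the raw matrix.
- `external` — one fit on all reference subjects, before CV. Test folds
  influence the transform.
- `external45` — per repetition, a fresh random `round(0.8 * n)` (round
  half to even) of the reference subjects *per site* is drawn and the model
  refit; still leaky, but with the reference sample size of the internal
  scheme, isolating "smaller reference" from "no leakage".
- `internal` — per fold, fit on training-fold reference subjects only and
  apply to that fold's train and test rows. A test subject whose site has
  no reference member in the training fold raises (it signals a broken
  plan, never silent passthrough).

## Evaluation protocols

**Case/control classification.** Per fold: the strategy's (train, test)
matrices are robust-scaled (training median subtracted, training IQR
divided; IQR = 75th − 25th percentile with linear interpolation; a zero IQR
leaves the scale at 1 so constant features stay finite), an RBF-kernel
soft-margin SVM is fit at default settings (`C = 1`,
`gamma = 1 / (p * Var(X_train))`), and test decision scores are reduced to
the rank-based AUC (ties count 1/2). Aggregation: mean and SD over all
k × R fold AUCs.

**Site-distinguishability audit.** TD subjects only; sites with at least 20
TD qualify; every unordered qualifying pair becomes a two-class problem on
the data the strategy would feed a classifier (the external variants
harmonize the full matrix up front, the 4/5 variant redrawing its reference
each repetition; the internal variant refits inside each training fold on
the two sites' training TD). Inside each fold the first 20 principal
components are estimated on the training rows (centering only — no robust
scaler here, where the classification protocol above does not apply) and
both splits are projected. Per-pair AUC is the mean over k × R folds;
the summary is the median and 25th/75th percentiles across pairs.

**Permutation importance.** For each fitted fold classifier: baseline test
AUC, then per feature the mean AUC over `n_shuffles = 5` within-test-fold
shuffles of that column; importance = baseline − mean shuffled AUC (no
retraining). Aggregation: mean over all folds; SD over the R per-repetition
means (sample SD); ranks descend by mean importance with ties broken by
feature name so rankings are strategy-independent. Top-30% sets use the
round-half-to-even count (`round(0.3 * 5253) = 1576`,
`round(0.3 * 221) = 66`). Cross-strategy agreement restricts to the
reference strategy's top set and reports product-moment correlations (a
Spearman option exists, since "correlation" is otherwise underdetermined),
the all-strategy intersection with percentage, per-feature C/NP marks, and
within-strategy fold-to-fold correlation matrices.

## Cohort selection

Two variants: `minSC` (males, ages 6–40, structural and functional
preprocessing both successful) and `fQC` (males, eyes-open, FIQ > 0,
preprocessing success, and mean framewise displacement not exceeding
median + 3·MAD over the post-filter candidate pool — one pooled rule, not
per site; MAD is unscaled, with the 1.4826 consistency factor exposed as an
option). High mean-FD means heavy motion, so the rule flags the upper tail
only. The age-window (9–20) and minimum-site-size (30) selection runs
*after* harmonization in the pipeline driver, so the age trend is estimated
on the widest available range; the driver's tests assert this ordering.
With fewer than three candidates the MAD rule is skipped (no scale to
estimate).

## Synthetic data: what it emulates, and what it does not

`generate_feature_matrix` draws exactly the harmonizer's generative model:
`gamma_iv ~ N(0, tau^2)`, `delta_iv^2` inverse-gamma with mean 1 (spread
parameter = SD of `delta^2`; 0 collapses to `delta = 1`), linear age slopes
`~ N(0, age_slope_sd)`, and an additive diagnosis effect of magnitude
`diag_effect_size` and random sign on a nearest-integer fraction of
features, recorded in the returned ground truth. Phenotypes include sex,
eye status, FIQ, preprocessing-success flags, and mean-FD with an injected
outlier fraction, so every selection filter is exercisable.
`generate_roi_timeseries` draws multivariate-normal series from a shared
base correlation matrix plus group/site perturbations on chosen ROI pairs,
repaired to a valid correlation matrix by eigenvalue clipping at 1e-8 and
diagonal renormalization; chosen ROIs can be zeroed to exercise null-ROI
pruning.

Defaults (the conditions all headline numbers are computed under): 4 sites
× 60 subjects, 50% cases, staggered 20-year age windows (sites differ in
median age), 50 features, site-location SD 3 (noise SD 1 — strong site
effects, calibrated only so that the unharmonized site audit is
near-perfect), `delta^2` spread 0.2, age-slope SD 0.05/year, diagnosis
effect 0.5 on 20% of features, 85% male, 80% eyes-open, FIQ 110 ± 15,
mean-FD median 0.10 with MAD 0.04 and 5% outliers.

What the generator does **not** contain: any subject-level biological
variance beyond the linear age trend. Harmonized synthetic data is
therefore almost pure noise, which has a visible consequence: effects that
real biological variance would dilute appear at full strength. In
particular, cross-validating signal-free data yields AUCs systematically
*below* chance (within a finite sample the realized test-fold class means
anti-correlate with the training folds'), and externally harmonized data —
where each site's full control mean has been removed exactly — shows this
reversal strongly: the external site-audit median lands around 0.36–0.44
rather than snapping to 0.5. The qualitative ordering
(none ≈ 1 > internal > external ≈ chance) is robust across seeds; the
exact distance of the external median from 0.5 is not a calibrated
quantity, and passing tests on this generator certify the machinery and
the ordering, not real-data effect sizes.

## Numerical and design choices

- Determinism: every stochastic step takes a seed; master seeds spawn
  per-repetition/per-pair children via `numpy.random.SeedSequence`, so any
  fold is re-runnable in isolation. Identical configuration ⇒ identical
  output, byte for byte.
- Percentiles (IQR, pair-AUC quartiles) use linear interpolation.
- Connectivity vectorization is strictly-upper-triangle, row-major, with
  `ROIi__ROIj` names — pinned so feature identities are stable across
  strategies.
- "Null" ROI series means identically-zero *or* constant (both make
  Pearson correlation undefined); the pruning threshold
  `max_null_fraction` defaults to 0.05.
- CV cells smaller than k are collapsed onto the class label (with a
  warning) so stratification degrades gracefully; if a whole class is
  smaller than k, plain shuffled folds are used.
- PCA requests beyond the available training rank are capped with a
  warning.
- The pipeline's external45 classification fits on the analysis-set
  controls (post age selection), matching the internal strategy's reference
  pool, whereas plain external fits on the wide-age variant set; this
  preserves the sample-size-matching purpose of the 4/5 scheme.

## Known limitations

- Covariates are linear only; no spline/GAM trends, no non-parametric EB,
  no longitudinal or image-level harmonization.
- The site audit's PCA-per-fold choice is one of two defensible readings
  (the alternative fits PCA on the full pair sample); fitting inside folds
  avoids adding a second leakage channel to the comparison.
- Real multi-site numerosities and effect sizes are not reproduced; the
  synthetic generator is a test harness with known truth, not a simulator
  of any particular collection.
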