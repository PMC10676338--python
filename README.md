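# combatcv

Multi-site case/control neuroimaging studies pool feature tables (cortical
thickness and volumes, functional-connectivity edges) from many acquisition
sites. Each site imprints additive and multiplicative *batch effects* on
every feature, strong enough that a classifier can identify the site almost
perfectly — and strong enough to contaminate any case/control analysis.
`combatcv` implements the standard remedy, ComBat harmonization fit on a
reference population of controls, together with the machinery needed to ask
the question practitioners usually skip: **where, relative to the
cross-validation loop, is the harmonizer allowed to be fit, and what does
that choice do to the results?**

The package is a library for:

- **Reference-population ComBat** — per feature *v*, site *i*, subject *j*:

  `y_ijv = α_v + x_ij' β_v + γ_iv + δ_iv ε_ijv`,  `ε_ijv ~ N(0, σ_v²)`

  with linear covariates (age by default; diagnosis never), parametric
  empirical-Bayes shrinkage of the per-site location/scale effects
  (Normal prior on γ, Inverse-Gamma on δ², moment-matched within site),
  all parameters estimated on typically-developing (TD) controls only, and
  the transform `y* = σ_v (z_ijv − γ*_iv)/δ*_iv + α_v + x_ij' β_v` applied
  to every subject.
- **Four deployment strategies** relative to a repeated, (class × site)-
  stratified k-fold CV plan: `none`, `external` (one fit on all controls
  before CV — leaky), `external45` (refit per repetition on a random 4/5 of
  controls per site — leaky, but with the reference sample size of the
  internal scheme), and `internal` (refit per fold on training-fold
  controls only — leakage-free).
- **A site-distinguishability audit** — pairwise TD-only site
  classification (RBF SVM on the first 20 principal components) reporting
  the median and quartiles of pair AUCs per strategy.
- **Case/control classification** — RBF SVM at default settings with
  fold-internal robust (median/IQR) scaling, AUC aggregated over k folds ×
  R repetitions.
- **Permutation feature importance** — test-fold AUC drop per feature,
  aggregated across the CV scheme, with top-30% selection and
  cross-strategy agreement analysis (correlations, common-feature counts,
  C/NP marks).
- **A synthetic multi-site generator** with known ground truth (site
  effects, age trend, a diagnosis effect on a known feature subset, and
  phenotype fields for every selection filter), so every claim above is
  testable without access to real multi-site data.

## Worked example

```bash
python examples/site_audit_strategies.py
```

generates a 4-site cohort (60 subjects per site, 50 features, site-effect
SD three times the noise SD) and audits how recognizable the sites remain
under each strategy:

```
      none: median pair AUC 1.00 [1.00; 1.00]
  external: median pair AUC 0.36 [0.30; 0.47]
external45: median pair AUC 0.44 [0.35; 0.53]
  internal: median pair AUC 0.66 [0.57; 0.70]
```

Raw data is perfectly site-separable. External harmonization — fit with the
eventual test subjects included — drives the audit to chance *and below it*
(a signature of leakage: once a site's full control mean is removed, test
folds anti-correlate with training folds). The leakage-free internal refit
genuinely reduces site information but cannot erase it for unseen subjects,
landing in between. `examples/classify_and_rank_features.py` runs the
case/control side on the same machinery:

```
     none: ASD/TD AUC 0.896 +/- 0.045
 external: ASD/TD AUC 0.906 +/- 0.055
 internal: ASD/TD AUC 0.906 +/- 0.054
top-30% set size: 9
importance correlation vs internal: {'none': 0.96, 'external': 1.0}
features common to all three top sets: 8 (89%)
```

Each `examples/*.py` script exercises one capability (simulation,
connectivity building, cohort selection, harmonization, the audit,
importance) and prints a short interpretation. A thin CLI mirrors the
library (`combatcv simulate | build-connectivity | select | harmonize |
classify | site-auc | importance | run-all`).

## Layout

```
src/combatcv/
  synthetic_data.py    cohort/feature/ROI-series generators + ground truth
  feature_builder.py   Pearson -> Fisher-z -> vectorized connectivity;
                       221-name structural schema; null-ROI pruning
  cohort_selection.py  minSC / fQC filters, MAD motion rule,
                       age-window + site-size selection
  harmonization.py     reference ComBat (EB location/scale) + 4 strategies
  evaluation.py        CV plans, robust scaling, RBF SVM, AUC, PCA,
                       site-distinguishability audit
  importance.py        permutation importance, top-30%, strategy agreement
  pipeline.py          end-to-end driver, TSV/JSON I/O
  cli.py               thin command-line layer
```

See `docs/methods.md` for the model, its assumptions, parameter defaults,
and known limitations.
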