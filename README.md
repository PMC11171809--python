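# cardiolos

A toolkit for modelling hospital length of stay (LOS) of cardiac inpatients
from EHR-style tabular data. Because real registries of this kind are
proprietary, the package ships a synthetic multi-table cohort generator with
planted, recoverable structure, so the entire pipeline is exercisable and
testable end to end.

## What's inside

| Module | Role |
|---|---|
| `cardiolos.synthetic_cohort` | Multi-table cohort generator (encounters, long-format labs, surgeries, prior admissions) with a lognormal-style LOS model driven by planted covariate effects and a latent 4-level severity class; truth sidecar for parameter recovery. |
| `cardiolos.feature_engineering` | Encounter filtering (adult cardiac inpatients, modelling years with a history index for excluded years) and derived features: admission/surgery history, vital in-range flags, latest-lab values and test counts, age. |
| `cardiolos.transforms` | `log1p` target transform, IQR winsorization (Tukey fences, capping at P10/P90), train-only min-max scaling, first-level-dropped dummy encoding, rule-based imputation, and equal-frequency quantile binning of the log stay into 4 classes. |
| `cardiolos.feature_selection` | Univariate scoring (Pearson \|r\| >= 0.1; Kruskal-Wallis and chi-square at p <= 0.05, paired by feature/target kind) and the FS-1..FS-10 subset registry with its union rule. |
| `cardiolos.learners` | Pluggable base learners: random forests, gradient-boosted trees, and a numpy two-hidden-layer MLP (per-layer dropout, tanh/swish/linear/relu, Adam, MAE loss); published-scale and desk-scale search spaces. |
| `cardiolos.cascade_ensembles` | The four ensemble architectures: averaging (`avg_vote`), two- and three-level sequential cascades (`seq2`, `seq3` — class probabilities, then an intermediate prediction, as meta-features), and the parallel cascade (`parallel`); plus a `single` baseline. |
| `cardiolos.evaluation` | MAE/MSE/RMSE/R2/Acc, seeded randomized hyperparameter search, stratified 5-fold nested CV with a leakage-instrumented fit log, error-day histograms and confusion profiles. |
| `cardiolos.pipeline` / `cardiolos.cli` | YAML-configured experiment runner and the `cardiolos` command-line interface. |

## CLI

```bash
cardiolos simulate --n-patients 1000 --seed 7 --out cohort/
cardiolos prepare --input cohort/ --out prepared/
cardiolos select-features --input prepared/features.csv \
    --meta prepared/features_meta.json --out registry.json
cardiolos all --config experiment.yaml
```

Example `experiment.yaml`:

```yaml
output_dir: out
seed: 42
simulate: {n_patients: 1500}
evaluation: {outer_folds: 5, n_iter: 5, inner_folds: 3, small_spaces: true}
cascades:
  - architecture: avg_vote
    name: avg-vote
    regressors:
      - {family: rf_regressor, feature_subset: FS-1, seed: 1}
      - {family: xgb_regressor, feature_subset: FS-1, seed: 2}
      - {family: ann_regressor, feature_subset: FS-1, seed: 3}
  - architecture: seq2
    name: cascade-2level
    classifier: {family: rf_classifier, feature_subset: FS-1, seed: 4}
    regressors:
      - {family: ann_regressor, feature_subset: FS-9, seed: 5}
```

## Notes

- Determinism: every stochastic step (generation, search, learners) is
  driven by explicit seeds; identical configs give byte-identical cohort
  CSVs and identical CV report JSON.
- Leakage: all fit/apply transforms and the hyperparameter search are fitted
  strictly inside the outer-training folds; the CV report logs the row ids
  touched at fit time so this is verifiable.
- Gradient boosting is provided by scikit-learn's
  `GradientBoostingRegressor`; the ANN is a self-contained numpy
  implementation so no deep-learning framework is required.
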