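# validstab

How much does the train/test split seed move your AUC? `validstab` is a
toolkit for quantifying the stability of classifier performance estimates
under different validation regimens on clinical-style tabular data:

- **Regimens** — stratified hold-out splits (50/50, 70/30), stratified
  10-fold CV with predictions *pooled* across folds into one global AUC,
  10× repeated 10-fold CV, 500× bootstrap out-of-bag validation, and
  leave-one-out.
- **ROC inference** — midrank Mann-Whitney AUC, ROC curves, DeLong
  structural-components variance and Wald confidence intervals,
  Hanley-McNeil standard errors, and a non-directional z-test between two
  independent ROC curves.
- **Stability harness** — replicate any regimen across seeds (splits held
  identical across classifiers), record the max/min AUC seeds, their
  DeLong CIs, the max-minus-min range, and the independent ROC comparison
  between the extreme seeds.
- **Synthetic cohorts** — a linear-logit generator (equicorrelated
  Gaussian + Bernoulli features, sparse alternating-sign coefficients,
  solved intercept, optional MCAR missingness) whose latent-score AUC can
  be calibrated to a target, standing in for private clinical datasets.
- **Classifiers** — logistic regression, Gaussian naive Bayes (native
  implementation), linear discriminant analysis and random forest (fixed
  internal random state), plus mutual-information feature ranking.

## Test

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (pair-enumeration AUC, double-loop
DeLong components), Monte-Carlo coverage/type-I-error checks, and a full
acceptance suite (`tests/test_acceptance.py`); it takes a few minutes on
one CPU.

## CLI

```sh
# generate a synthetic cohort (spec JSON -> CSV + sidecar spec record)
validstab generate --config cohort_spec.json --seed 0 --out cohort.csv

# apply a missing-data policy
validstab preprocess --input cohort.csv --policy drop --out clean.csv

# full stability experiment from a config (or a shipped preset)
validstab run --preset primary_cohort --out results/primary
validstab run --config my_config.json

# re-print the summary table of a finished run
validstab report --run-dir results/primary
```

A run writes `table.csv` (max/min AUC with DeLong CIs and significance
stars), `ranges.csv` (long-format AUC ranges), `aucs_<regimen>.csv`
(seed × classifier matrices), `reports.json`, and `run_log.json` (full
effective configuration, for reproducibility). Re-running an identical
config reproduces identical CSVs byte for byte.

Two presets ship with the package: `primary_cohort` (n=715→681 after
complete-case filtering, 54% prevalence, 30 features) and
`secondary_cohort` (n=2691, 19% prevalence, 27 features, mean
imputation). Both replicate the full study design — 4 classifiers × 6
regimens × 100 seeds, including 500× bootstrap and LOO — so a complete
preset run takes hours on one CPU; trim `n_seeds` or the regimen list for
a quick look.

Note: by design the `impute` policy computes column means over the full
dataset before splitting — a faithful reproduction of a
preprocess-then-validate pipeline, which leaks test information.
`mean_impute(data, fit_rows=...)` offers a train-only mode.

## Python API

```python
import dataclasses
from validstab import (
    CohortSpec, calibrate_effect_scale, generate_cohort,
    make_classifier, run_stability, summarize_table,
)

spec = CohortSpec(n_patients=681, prevalence=0.54,
                  n_continuous=20, n_binary=10, seed=0)
scale = calibrate_effect_scale(spec, target_auc=0.80)
data = generate_cohort(dataclasses.replace(spec, effect_scale=scale))

classifiers = [make_classifier(n, internal_seed=0)
               for n in ("logistic", "gnb", "lda", "random_forest")]
reports = run_stability(data, classifiers, "split7030", n_seeds=100)
print(summarize_table(reports))
```
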