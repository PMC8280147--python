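{
  "dataset": {
    "cohort": {
      "n_patients": 715,
      "prevalence": 0.54,
      "n_continuous": 20,
      "n_binary": 10,
      "feature_correlation": 0.2,
      "target_auc": 0.8,
      "missing_fraction": 0.0476,
      "seed": 0
    }
  },
  "preprocessing": "drop",
  "classifiers": [
    {"name": "logistic"},
    {"name": "gnb"},
    {"name": "lda"},
    {"name": "random_forest", "internal_seed": 0}
  ],
  "regimens": [
    {"name": "split5050"},
    {"name": "split7030"},
    {"name": "kfold10", "k": 10},
    {"name": "repeated10x10", "k": 10, "repeats": 10},
    {"name": "bootstrap500", "n_reps": 500},
    {"name": "loo"}
  ],
  "n_seeds": 100,
  "comparison_method": "hanley_mcneil",
  "feature_selection": null,
  "output_dir": "results/primary_cohort"
}
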