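"""The core experiment: does filtering out low-robustness features make
models more robust and more generalizable?

Runs the full pipeline on the canonical synthetic cohort (200 patients, 300
features with known robustness structure, 20 perturbation replicates): per
CV split, feature ICC is computed on the training side only, features are
filtered at ICC > 0 / 0.75 / 0.95, selected (bootstrap-ANOVA ranking +
correlation pruning, max 10), and a ridge classifier is trained and scored.
"""

from robustrad import (CVScheme, ExperimentConfig, generate_benchmark_tables,
                       run_experiment)

features, replicates, labels, truth = generate_benchmark_tables(seed=0)
print(f"cohort: {len(labels)} patients, {int(labels.sum())} events, "
      f"{features.shape[1]} features "
      f"({int(truth['informative'].sum())} informative)")

config = ExperimentConfig(thresholds=(0.0, 0.75, 0.95),
                          classifiers=("ridge",),
                          cv=CVScheme(folds=2, repetitions=10), seed=0)
records, comparisons = run_experiment(features, replicates, labels, config)

summary = records.assign(absgap=records["gap"].abs()).groupby(
    "threshold")[["train_auc", "test_auc", "model_icc", "absgap"]].mean()
print("\nmean metrics per robustness-filtering threshold:")
print(summary.round(3).to_string())
print("\npaired t-tests against the unfiltered baseline:")
print(comparisons[["threshold", "t_icc", "p_icc", "t_absgap",
                   "p_absgap"]].round(4).to_string(index=False))
# Expected direction: model ICC (prediction stability under perturbation)
# rises with the threshold, and the train-test AUC gap (overfitting to the
# training half) shrinks -- the same pattern reported on real head-and-neck
# CT cohorts.  Training AUC drops because the candidate pool shrinks.
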