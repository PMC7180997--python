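"""Leave-two-subjects-out cross-validation of the classifier roster.

Simulates the full 5-sham/4-TBI cohort (shortened to 1-hour recordings),
then runs the exhaustive 20-fold protocol — every (sham, TBI) pair held
out once — for three classifiers under two normalization scenarios.
Accuracy is per epoch, pooled over the two held-out subjects.
"""

from wakeqeeg import CohortSpec, ModelSpec, RunConfig, run_experiment, simulate_cohort

spec = CohortSpec(duration_h=1.0, seed=1, subject_gain_sd_db=3.0)
cohort = simulate_cohort(spec)

config = RunConfig(epoch_length_min=1, seed=1)
report = run_experiment(
    config,
    cohort,
    models=[ModelSpec("knn7"), ModelSpec("rf"), ModelSpec("svm")],
    scenarios=["none", "decibel_plus_feature"],
)

summary = report.summary()
print(summary.round(2).to_string(index=False))
print(
    "\nEach row aggregates 20 folds: the mean per-epoch accuracy (%) and the"
    "\npopulation variance of fold accuracies. With 3 dB of broadband gain"
    "\njitter between subjects, the decibel-normalized features typically"
    "\nclassify better than raw band powers."
)
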