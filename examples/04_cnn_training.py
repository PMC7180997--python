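"""Train the 1-D convolutional network on windowed spectral features.

Each 1-min epoch becomes a sequence of 119 windows x 5 dB-normalized
band powers (1-s window, 0.5-s step). The network - two conv/max-pool
blocks, batch norm, a 40-unit dense layer with L1 penalty, softmax - is
trained with Adam and early stopping on one cross-validation fold.
"""

import numpy as np

from wakeqeeg import CohortSpec, ModelSpec, RunConfig, run_experiment, simulate_cohort
from wakeqeeg.cnn import forward_shapes

spec = CohortSpec(
    duration_h=1.0, seed=3, subject_gain_sd_db=0.0,
    effect_db={"alpha": -6.0, "theta": 6.0},
)
cohort = simulate_cohort(spec)

shapes = forward_shapes(119)
print("temporal length through the network:", {"input": 119, **shapes})

config = RunConfig(epoch_length_min=1, seed=3)
report = run_experiment(
    config, cohort, [ModelSpec("cnn")], fold_subset=[0],
    cnn_kwargs={"max_epochs": 120},
)
row = report.results.iloc[0]
print(
    f"\nfold 0 (held out: {row['test_sham']}, {row['test_tbi']}): "
    f"per-epoch accuracy {row['accuracy_pct']:.1f}%"
)
print(
    "\nThe held-out subjects were never seen during training or"
    "\nnormalization fitting; accuracy well above 50% means the network"
    "\ngeneralizes the injected spectral signature across subjects."
)
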