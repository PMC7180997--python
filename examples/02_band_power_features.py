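"""Turn wake epochs into the six-feature qEEG representation.

Simulates a small cohort with the default group effects (TBI: alpha
-3 dB, theta +3 dB), extracts 1-min wake epochs, and builds features
under the decibel-plus-feature normalization: band powers are expressed
in dB relative to a baseline fitted from the first five epochs of each
training subject, then z-scored with training-set statistics.
"""

import pandas as pd

from wakeqeeg import CohortSpec, build_features, extract_wake_epochs, simulate_cohort

pd.set_option("display.width", 120)

spec = CohortSpec(n_sham=3, n_tbi=2, duration_h=1.0, seed=7)
epochsets = [extract_wake_epochs(rec, hyp, 1) for rec, hyp in simulate_cohort(spec)]

table, params = build_features(epochsets, scenario="decibel_plus_feature")
print("fitted per-band decibel baselines (raw power units):")
for band, value in params.db_baseline.items():
    print(f"  {band:6s} {value:10.2f}")

print("\nfirst feature rows (z-scored dB values):")
print(table.data.head(8).round(2).to_string(index=False))

means = table.data.groupby("group")[["theta", "alpha"]].mean().round(2)
print("\ngroup means of the two affected features:")
print(means.to_string())
print(
    "\nTBI rows sit higher in theta and lower in alpha than sham rows —"
    "\nthe injected spectral signature, now visible on a common scale."
)
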