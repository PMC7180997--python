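# Methods

This note documents the models, numerical choices and design decisions
behind `wakeqeeg`, and what its synthetic experiments do and do not show.

## Signal model of the synthetic cohort

Each subject's recording is a sum of

1. a **1/f-type background**: Gaussian noise spectrally shaped to a power
   density ∝ 1/f^`background_slope` (default slope 1, RMS 0.1 before
   amplitude calibration). Its role is a broadband floor; its in-band
   contribution is kept small so band powers track the configured gains.
2. **five band-limited components**: white noise passed through the *same*
   6th-order Butterworth filter bank the feature extractor uses, each
   normalized to unit RMS per realization and scaled to a target power in
   dB. Filtering with the analysis bank guarantees injected effects live
   exactly where the features look, which makes parameter recovery a
   clean test. Default band gains decline ≈ 25 dB from theta to gamma
   (0, −7, −13, −18, −25 dB), mimicking the steep 1/f fall-off of real
   rodent EEG; the whole signal is scaled to a microvolt-like RMS
   (`amplitude_scale = 30`) so raw band powers span ~30–900 squared
   units, the dynamic range an un-normalized feature space actually has.

On top of the static gains:

* **group effect** (`effect_db`, default alpha −3 dB / theta +3 dB for
  TBI): the direction of the spectral signature; magnitude is
  configurable because only the direction, not the size, is established.
* **subject broadband gain jitter** (`subject_gain_sd_db`, default
  1.5 dB, one draw per subject): electrode impedance / amplifier gain
  differences, spectrally flat. This is the nuisance decibel
  normalization targets: a log transform turns it into an additive
  offset common to all bands, and the alpha:theta contrast is exactly
  invariant to it. A `subject_band_sd_db` knob (default 0) adds
  per-band subject offsets for experiments on spectral-shape
  heterogeneity.
* **slow band-power drift** (`band_fluct_sd_db` = 2 dB, AR(1) at 4-s
  resolution with a 4-min correlation time): real band power is not
  stationary — behavioural state moves it by several dB over minutes.
  Without this term every per-epoch feature would be implausibly
  noise-free and any single feature would classify perfectly.
* **artifact bursts** during wake: *movement* artifacts hit theta+alpha
  (12 ± 3 dB on 8 % of 4-s scores), *EMG bleed* hits sigma/beta/gamma
  (18 ± 3 dB on 15 % of scores) — the classic contamination of 30–35 Hz
  EEG in behaving rodents. One magnitude is drawn per event and shared
  by the event's bands. The pipeline deliberately performs no artifact
  rejection, so these heavy multiplicative tails reach the features;
  taming them is precisely what a logarithmic representation is for.
* a fixed **wake-vs-sleep tilt** (theta −2, beta/gamma +1.5 dB during W)
  so stages are spectrally distinct.

Hypnograms are Markov chains over {W, NREM, REM} at 4-s resolution. The
default transition matrix gives mean bouts of ≈ 8 min (wake), ≈ 8.7 min
(NREM) and ≈ 1.2 min (REM) and a stationary wake fraction of ≈ 0.45;
24-h hypnograms then yield on the order of 600 one-minute wake epochs per
subject, inside the 200–920 range reported for real mice, and counts fall
roughly proportionally at 2 and 4 min. Bout statistics, not recording
length, set the epoch yield, so tests run on 1–4-h recordings.

Determinism: each subject draws from an independent `SeedSequence`
substream of the cohort seed; identical `(spec, seed)` give byte-identical
cohorts.

## Feature pipeline

* **Epoching** is a greedy left-to-right scan: k = 15 × minutes
  consecutive W scores yield an epoch, any non-W score resets the run,
  epochs are run-aligned (they start at a maximal run's first score).
  This equals packing ⌊run/k⌋ epochs into each maximal W run, and epochs
  never straddle even a single sleep score.
* **Power estimate**: full-length DFT (15 360 points for 1 min at 256 Hz),
  mean squared magnitude with 1/N² bin scaling — identically the
  time-domain mean square (Parseval), asserted to 1e-9 in tests. No
  windowing or tapering is applied.
* **Filtering** is zero-phase (forward–backward second-order sections).
  The effective magnitude response is the square of the one-pass
  Butterworth response; in-band gain stays ≈ 1 while stop-band rejection
  doubles in dB. Filter edge transients touch only the outermost windows
  of the CNN front end (≈ 1 dB on a stationary tone).
* **Decibel baseline**: pooled mean raw power of the first k epochs of
  every *training* subject (k = 5 default, k = 1 under the `first_epoch`
  policy; the per-subject-then-pooled reading of an ambiguous design
  choice). Held-out subjects never contribute. Note that for z-scored
  scenarios the baseline is absorbed by the subsequent standardization
  (an affine shift per feature); it matters substantively for the CNN
  front end, whose windowed dB features are not z-scored.
* **alpha:theta ratio**: always formed from raw band powers. Under
  decibel normalization it is expressed in the log domain,
  10·log10(alpha/theta) — the dB difference of the two bands — keeping
  all six features in one additive noise family; a linear quotient of
  lognormal powers is heavy-tailed and ill-conditioned for
  distance-based classifiers. `ratio_domain="linear"` restores the
  plain quotient.
* **z-scoring** uses training-set mean and population SD; a feature whose
  SD is numerically zero (relative tolerance 1e-12) is scaled by 1 with
  a logged warning.

## Classifiers

Hyperparameters pinned for reproducibility where the study design is
silent: DT Gini/unlimited depth; RF 100 trees; SVM C = 1, RBF kernel with
scale-set width; KNN Euclidean, uniform weights; MLP (5, 5) ReLU/Adam,
≤ 2000 iterations. Training rejects single-class folds. Per-epoch
prediction throughout; test epochs of the two held-out subjects are
pooled for the fold accuracy (per-subject accuracies are also logged).

The CNN is implemented directly in NumPy (forward/backward passes, Adam,
batch norm, early stopping), which keeps it dependency-free and
bit-reproducible from its seed. Architecture: conv(16 filters, kernel 4,
ReLU) → max-pool 2 → conv(16, 4, ReLU) → max-pool 2 → channel batch-norm
→ dense 40 (L1 10⁻³) → softmax 2. Temporal lengths: 119→116→58→55→27
(1 min), 239→…→57 (2 min), 479→…→117 (4 min); only the dense fan-in
depends on the input length. Training: categorical cross-entropy, Adam
lr 10⁻³, batch 32, ≤ 500 epochs, early stopping with patience 50 on the
validation loss of a 10 % stratified split, best-validation weights
restored. The prose description of the output layer in the source design
is contradictory (max-pool vs softmax); softmax is implemented. Its
windowed features are always decibel-normalized with the training
baseline, independent of the rule-based scenario — the representation the
network was designed for. The "20 iterations" of the source design is
read as the 20 cross-validation trials, not 20 gradient epochs.

## Cross-validation and reporting

Folds are the exhaustive Cartesian product of one held-out sham × one
held-out TBI subject, in lexicographic order (5 × 4 = 20; the count
identity makes the exhaustive reading of "20 trials" compelling).
Cross-fold variance is the *population* variance of %-valued fold
accuracies (fold accuracies {60, 80} → variance 100). Within a fold all
models share the same transformed features, so model comparisons isolate
the classifier. Class imbalance between sham and TBI epochs is left
unweighted.

## What the synthetic experiments show — and don't

The generator reproduces the statistical *structure* the analysis relies
on (spectral effects where the features look, broadband subject nuisance,
heavy-tailed wake artifacts, realistic epoch yields), not mouse
neurophysiology: there are no oscillatory bouts, no spindles, no
scorer noise on stage labels, and artifact bursts are stylized
rectangular events. Passing tests therefore demonstrate that the
*pipeline* is correct and that its normalization behaves as designed
under the stated nuisance model — they do not certify accuracy levels on
real recordings, and none of the original study's accuracy figures are
reproduction targets (its recordings are not public).

Benchmark conditions (chosen once; desk-scale sizes keep any experiment
within minutes on one CPU):

* **parameter recovery**: 2-h recordings, alpha −6 / theta +6 dB, no
  subject gain jitter — every classifier should exceed 90 % over the 20
  folds (typically 94–97 %).
* **chance control**: zero effects, no jitter, 4-h recordings. The
  longer duration matters: at 2 h the per-subject AR-drift means do not
  fully average out and can masquerade as a weak group signal in either
  direction; at 4 h all models sit within a few points of 50 %.
* **normalization benefit**: ±2 dB effects under 3 dB broadband jitter,
  KNN7, five independent cohorts — decibel + feature normalization beats
  raw features in ≥ 4 of 5 replicates (mean gap ≈ +4–5 points). The gap
  is driven jointly by the log-domain contrast's invariance to broadband
  gain and by variance stabilization of the artifact tails; with milder
  artifact or drift settings the two scenarios converge.
* **CNN benchmark**: the recovery cohort on a 4-fold subset
  (folds 0/5/10/15, one appearance per sham subject) — ≥ 85 %, typically
  ≥ 95 %. The subset bounds runtime; the network is the costly model.

## Known limitations

* Single channel only; no montage or re-referencing logic.
* EDF files are read (via `mne`) but not written; the native interchange
  format is raw float32 + JSON sidecar.
* The Markov hypnogram has geometric bout lengths; real bout-length
  distributions are heavier-tailed.
* KNN distance ties at exactly equal distances follow scikit-learn's
  stable neighbor ordering; with continuous features ties have measure
  zero, and the brute-force equivalence tests use such data.
* Batch-norm statistics make CNN training mildly batch-size dependent;
  determinism holds for a fixed seed and configuration.
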