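# wakeqeeg

Quantitative-EEG classification of mild traumatic brain injury (mTBI) from
single-channel rodent sleep EEG.

After a mild brain injury, the wake EEG of mice carries a subtle spectral
signature — attenuated alpha-band power and elevated theta-band power.
`wakeqeeg` implements a complete, tested pipeline for detecting that
signature with machine learning: synthetic sleep-EEG cohort simulation,
wake-epoch extraction from hypnograms, band-power feature building with
decibel baseline normalization, a roster of classical classifiers plus a
small 1-D convolutional network, and a subject-wise cross-validation
protocol that never lets information leak from held-out animals. It is
aimed at researchers benchmarking qEEG biomarkers or normalization schemes
when no public recordings are available.

## The method

A 24-h single-channel recording at 256 Hz comes with a hypnogram: one label
in {W, NREM, REM} per 4-s score. Non-overlapping **wake epochs** (1, 2 or
4 min) are extracted greedily from unbroken runs of W scores. Each epoch is
band-pass filtered (6th-order Butterworth, zero-phase) into five bands —
theta 4–7.5, alpha 8–12, sigma 13–16, beta 16.5–25, gamma 30–35 Hz — and
each band's **average power** is the mean over DFT bins of the squared
magnitude, which by Parseval's theorem equals the time-domain mean square.

Band powers are **decibel-normalized** against a baseline fitted on
training subjects only (the pooled mean power of each subject's first five
epochs):

```
dB = 10 · log10(activity / baseline)
```

The sixth feature is the alpha:theta power ratio (expressed in the log
domain under decibel normalization). All features are then z-scored with
training-set mean and SD. Classifiers: decision tree, random forest,
RBF-kernel SVM, KNN with k ∈ {3, 5, 7}, a (5, 5) multilayer perceptron,
and a 1-D CNN that instead consumes a sliding-window representation
(1-s windows, 0.5-s step → 119 windows × 5 dB band powers per 1-min epoch)
through two conv/max-pool blocks, batch normalization, a 40-unit dense
layer with L1 = 0.001 and a softmax head (Adam, early stopping with
patience 50 on a 10 % validation split).

Evaluation is **leave-two-subjects-out**: every (sham, TBI) pair is held
out once — 20 folds for 5 sham + 4 TBI animals — and accuracy is per epoch,
`(TP + TN) / N`, pooled over the two held-out subjects. All normalization
statistics are re-fitted inside each fold from the training subjects alone.

Because no recordings are deposited with the study design this package
follows, a first-class **synthetic cohort generator** provides the data:
1/f background plus band-limited Gaussian components with configurable
per-band gains, group effects in dB, per-subject broadband gain jitter,
slow AR(1) band-power drift, and band-selective movement/EMG artifact
bursts. Every generated cohort is bit-reproducible from its seed.

## Worked example

`examples/03_cross_validation.py` simulates the 9-subject cohort with 3 dB
of broadband gain jitter between subjects and cross-validates three models
under two normalization scenarios:

```
model             scenario  epoch_length_min  mean_accuracy_pct  variance_pct  n_folds
 knn7 decibel_plus_feature                 1              86.19         29.56       20
 knn7                 none                 1              72.77        241.87       20
   rf decibel_plus_feature                 1              88.87         30.87       20
   rf                 none                 1              88.72         34.05       20
  svm decibel_plus_feature                 1              87.22         32.54       20
  svm                 none                 1              67.06        376.21       20
```

Each row aggregates the 20 folds: mean per-epoch accuracy (%) and the
population variance of fold accuracies. Decibel + feature normalization
lifts the distance- and margin-based models (KNN, SVM) well above raw
band powers and makes fold-to-fold results far more stable — the core
claim this pipeline exists to test. The other examples cover cohort
simulation (`01`), feature building (`02`) and CNN training (`04`).

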