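"""Classifier roster and the windowed spectral front end for the CNN.

Six classical per-epoch classifiers behind one train/predict contract:
decision tree (dt), random forest (rf), RBF-kernel support vector machine
(svm), K-nearest neighbors with k in {3, 5, 7} (knn3/knn5/knn7) and a
small multilayer perceptron with two hidden layers of 5 units (nn).
Hyperparameters not pinned by the study design are fixed here so runs are
reproducible: Gini/unlimited-depth trees, 100-tree forest, SVM C=1 with
scale-set kernel width, Euclidean uniform-weight KNN, ReLU/Adam MLP with
up to 2000 iterations.

The convolutional model consumes a different representation: a 1-s window
slides over each epoch with 0.5-s steps and the five band-average powers
are computed per window (decibel-normalized against the training
baseline), giving a (windows x 5) sequence per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .epoching import EpochSet
from .features import FeatureTable, band_definitions, design_bandpass

RULE_BASED_MODELS = ("dt", "rf", "svm", "knn3", "knn5", "knn7", "nn")
ALL_MODELS = RULE_BASED_MODELS + ("cnn",)


@dataclass
class ModelSpec:
    """A named classifier with optional hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ALL_MODELS:
            raise ValueError(f"unknown model {self.name!r}; choose from {ALL_MODELS}")


def _make_estimator(spec: ModelSpec):
    name, hp, seed = spec.name, spec.hyperparameters, spec.seed
    if name == "dt":
        return DecisionTreeClassifier(criterion="gini", random_state=seed, **hp)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, **hp)
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed, **hp)
    if name.startswith("knn"):
        k = int(name[3:])
        return KNeighborsClassifier(
            n_neighbors=k, weights="uniform", metric="euclidean", **hp
        )
    if name == "nn":
        return MLPClassifier(
            hidden_layer_sizes=(5, 5), activation="relu", solver="adam",
            max_iter=2000, random_state=seed, **hp
        )
    raise ValueError(f"{name!r} is not a rule-based model")


def train_rule_based(spec: ModelSpec, train: FeatureTable):
    """Fit one classical classifier on a (training) feature table."""
    y = train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    est = _make_estimator(spec)
    est.fit(train.X, y)
    return est


def predict(model, table: FeatureTable) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-epoch labels and, where supported, P(tbi) scores in [0, 1]."""
    if len(table) == 0:
        return np.empty(0, dtype=int), None
    X = table.X
    n_expected = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != n_expected:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} != model expects {n_expected}"
        )
    labels = np.asarray(model.predict(X), dtype=int)
    scores = None
    if hasattr(model, "predict_proba"):
        try:
            proba = model.predict_proba(X)
            classes = list(getattr(model, "classes_", [0, 1]))
            scores = proba[:, classes.index(1)]
        except Exception:
            scores = None
    return labels, scores


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of correct per-epoch predictions, (TP + TN) / N."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    return float(np.mean(predicted == truth))


# ---------------------------------------------------------------------------
# Windowed spectral features for the convolutional model


@dataclass
class WindowedEpoch:
    """One epoch as an ordered (n_windows, 5) sequence of band powers."""

    windows: np.ndarray
    window_s: float = 1.0
    step_s: float = 0.5

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 2:
            raise ValueError("windows must be 2-D (n_windows, n_bands)")


def window_count(n_samples: int, fs: float, window_s: float = 1.0,
                 step_s: float = 0.5) -> int:
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if n_samples < win:
        raise ValueError("epoch shorter than one window")
    return (n_samples - win) // step + 1


def windowed_band_powers(
    epoch: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    window_s: float = 1.0,
    step_s: float = 0.5,
) -> np.ndarray:
    """Raw per-window mean band powers, shape (n_windows, n_bands).

    The epoch is band-pass filtered once per band over its full length
    (avoiding per-window filter edge effects); each window's mean power is
    then the windowed mean square of the filtered trace, computed via a
    cumulative sum. A 60-s epoch yields 119 windows at any sampling rate.
    """
    epoch = np.asarray(epoch, dtype=float)
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    n_win = window_count(epoch.size, fs, window_s, step_s)
    starts = np.arange(n_win) * step
    out = np.empty((n_win, len(band_definitions(bands))), dtype=float)
    for j, band in enumerate(band_definitions(bands)):
        sos = design_bandpass(band, fs)
        filtered = _signal.sosfiltfilt(sos, epoch)
        csum = np.concatenate([[0.0], np.cumsum(filtered**2)])
        out[:, j] = (csum[starts + win] - csum[starts]) / win
    return out


def windowed_features(
    epoch: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    db_baseline: dict[str, float] | None = None,
    window_s: float = 1.0,
    step_s: float = 0.5,
) -> WindowedEpoch:
    """Sliding-window band powers for one epoch, optionally in dB.

    When ``db_baseline`` (the training-set per-band baseline) is given,
    each window power is expressed as 10*log10(power/baseline) — the
    normalization that lets the convolutional model generalize across
    subjects.
    """
    powers = windowed_band_powers(epoch, fs, bands, window_s, step_s)
    if db_baseline is not None:
        names = [b.name for b in band_definitions(bands)]
        base = np.array([db_baseline[n] for n in names])
        powers = 10.0 * np.log10(powers / base)
    return WindowedEpoch(windows=powers, window_s=window_s, step_s=step_s)


def windowed_tensor(
    epochset: EpochSet,
    bands: dict[str, tuple[float, float]] | None = None,
    window_s: float = 1.0,
    step_s: float = 0.5,
) -> np.ndarray:
    """Raw window powers for a whole EpochSet: (n_epochs, n_windows, n_bands)."""
    if len(epochset) == 0:
        n_bands = len(band_definitions(bands))
        return np.empty((0, 0, n_bands))
    return np.stack(
        [
            windowed_band_powers(e, epochset.fs, bands, window_s, step_s)
            for e in epochset.epochs
        ]
    )
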