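"""Band-power features with decibel baseline and z-score normalization.

Each wake epoch is summarized by the mean power in five frequency bands
(theta 4-7.5, alpha 8-12, sigma 13-16, beta 16.5-25, gamma 30-35 Hz),
obtained by 6th-order Butterworth band-pass filtering followed by a
full-length DFT power estimate, plus the alpha:theta power ratio.

Three normalization scenarios are supported:

``none``
    raw band powers and the raw alpha:theta ratio;
``feature_only``
    each feature z-scored with mean/SD fitted on training rows only;
``decibel_plus_feature``
    band powers first expressed in decibels relative to a baseline power
    (``10*log10(activity/baseline)``) fitted on training subjects, then
    z-scored.

The decibel baseline compensates both for the 1/f decline of EEG power
with frequency and for broadband gain differences between subjects
(electrode impedance, amplifier gain); it is the step that lets a model
trained on some subjects transfer to unseen ones.  All statistics — the
per-band baselines and the per-feature mean/SD — are fitted on training
subjects only and reused unchanged on held-out subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .epoching import EpochSet
from .io import BASELINE_POLICIES, DEFAULT_BANDS, SCENARIOS

logger = logging.getLogger("wakeqeeg")

FEATURE_NAMES = ["theta", "alpha", "sigma", "beta", "gamma", "alpha_theta_ratio"]


@dataclass(frozen=True)
class BandDefinition:
    """A named band-pass specification for the Butterworth filter bank."""

    name: str
    low_hz: float
    high_hz: float
    filter_order: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )


def band_definitions(
    bands: dict[str, tuple[float, float]] | None = None, filter_order: int = 6
) -> list[BandDefinition]:
    bands = DEFAULT_BANDS if bands is None else bands
    return [BandDefinition(n, lo, hi, filter_order) for n, (lo, hi) in bands.items()]


def design_bandpass(band: BandDefinition, fs: float) -> np.ndarray:
    """Second-order-section Butterworth band-pass for ``band`` at rate ``fs``."""
    nyq = fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high_hz} Hz >= Nyquist {nyq} Hz"
        )
    return signal.butter(
        band.filter_order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(epoch: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band-pass filter of one segment.

    Forward-backward application (``sosfiltfilt``) gives zero phase lag at
    the cost of squaring the magnitude response; band power of in-band
    content is essentially unchanged while stop-band rejection doubles in
    dB terms.
    """
    epoch = np.asarray(epoch, dtype=float)
    sos = design_bandpass(band, fs)
    return signal.sosfiltfilt(sos, epoch)


def mean_power(segment: np.ndarray, n_dft: int | None = None) -> float:
    """Mean power of a segment from its DFT.

    The power estimate is the mean over all DFT bins of the squared
    magnitude with 1/N^2-normalized bins, which by Parseval's theorem
    equals the time-domain mean squared amplitude.  ``n_dft`` defaults to
    the full segment length (15 360 points for a 1-min epoch at 256 Hz);
    a shorter ``n_dft`` truncates, a longer one zero-pads.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("cannot compute power of an empty segment")
    n = segment.size if n_dft is None else int(n_dft)
    if n <= 0:
        raise ValueError("n_dft must be positive")
    spectrum = np.fft.fft(segment, n=n)
    return float(np.mean(np.abs(spectrum) ** 2) / n)


def db_normalize(activity: float | np.ndarray, baseline: float | np.ndarray):
    """Decibel change of ``activity`` relative to ``baseline``:
    ``10*log10(activity/baseline)``.

    Both inputs must be strictly positive; this never silently returns
    ``-inf``.
    """
    activity = np.asarray(activity, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(activity <= 0) or np.any(baseline <= 0):
        raise ValueError("db_normalize requires strictly positive powers")
    out = 10.0 * np.log10(activity / baseline)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Raw band-power tables

POWER_META = ["subject", "group", "epoch_index"]


def band_power_table(
    epochsets: list[EpochSet],
    bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Raw per-epoch mean band powers for one or more subjects.

    Returns a tidy frame with columns ``subject, group, epoch_index`` plus
    one raw (un-normalized) power column per band, epochs in extraction
    order. This is the single expensive step (filtering); everything
    downstream (baselines, scenarios) reuses the table.
    """
    defs = band_definitions(bands)
    rows = []
    for es in epochsets:
        sos_bank = [design_bandpass(b, es.fs) for b in defs]
        for i, epoch in enumerate(es.epochs):
            row: dict = {
                "subject": es.subject_id,
                "group": es.group,
                "epoch_index": i,
            }
            for b, sos in zip(defs, sos_bank):
                filtered = signal.sosfiltfilt(sos, epoch)
                row[b.name] = mean_power(filtered)
            rows.append(row)
    columns = POWER_META + [b.name for b in defs]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class NormalizationParams:
    """Training-set statistics for the decibel and z-score steps.

    ``db_baseline`` maps band name to the pooled mean raw power of the
    first-k epochs of every training subject (k=5 or 1 by policy);
    ``feat_mean``/``feat_sd`` are per-feature z-scoring statistics.  Test
    subjects never contribute to any of these.
    """

    scenario: str = "decibel_plus_feature"
    baseline_policy: str = "first_5_epochs"
    ratio_domain: str = "linear"
    db_baseline: dict[str, float] | None = None
    feat_mean: pd.Series | None = None
    feat_sd: pd.Series | None = None
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    @property
    def fitted(self) -> bool:
        if self.scenario == "none":
            return True
        if self.scenario == "feature_only":
            return self.feat_mean is not None
        return self.db_baseline is not None and self.feat_mean is not None


def baseline_epoch_count(policy: str) -> int:
    if policy not in BASELINE_POLICIES:
        raise ValueError(f"unknown baseline policy {policy!r}")
    return 5 if policy == "first_5_epochs" else 1


def fit_baseline_from_table(
    power_table: pd.DataFrame, policy: str = "first_5_epochs"
) -> dict[str, float]:
    """Per-band decibel baselines from a raw power table of training subjects.

    For each band the baseline is the mean raw power over the first k
    epochs of *every* training subject, pooled (k x n_train epochs in
    total).  A training subject with fewer than k epochs is an error.
    """
    k = baseline_epoch_count(policy)
    band_cols = [c for c in power_table.columns if c not in POWER_META]
    selected = []
    for subject, sub in power_table.groupby("subject", sort=False):
        sub = sub.sort_values("epoch_index")
        if len(sub) < k:
            raise ValueError(
                f"training subject {subject!r} has only {len(sub)} epochs; "
                f"baseline policy {policy!r} needs {k}"
            )
        selected.append(sub.iloc[:k])
    pooled = pd.concat(selected)
    return {c: float(pooled[c].mean()) for c in band_cols}


def fit_baseline(
    train_epochsets: list[EpochSet],
    policy: str = "first_5_epochs",
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Convenience wrapper: compute powers for training subjects, then fit."""
    return fit_baseline_from_table(band_power_table(train_epochsets, bands), policy)


@dataclass
class FeatureTable:
    """Per-epoch feature matrix with labels and provenance.

    ``data`` holds ``subject, group`` plus the six feature columns
    (five band powers and the alpha:theta ratio) under the applied
    normalization scenario.
    """

    data: pd.DataFrame
    scenario: str
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_names if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        if self.data[self.feature_names].isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Labels: sham=0, tbi=1."""
        return (self.data["group"].to_numpy() == "tbi").astype(int)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _raw_feature_frame(power_table: pd.DataFrame) -> pd.DataFrame:
    """Raw band powers + alpha:theta ratio from raw powers."""
    out = power_table.copy()
    out["alpha_theta_ratio"] = out["alpha"] / out["theta"]
    return out


def features_from_table(
    power_table: pd.DataFrame,
    params: NormalizationParams | None = None,
    scenario: str = "decibel_plus_feature",
    baseline_policy: str = "first_5_epochs",
    ratio_domain: str = "log",
) -> tuple[FeatureTable, NormalizationParams]:
    """Build a feature table from raw band powers under a scenario.

    With ``params=None`` the rows are treated as the training set and all
    normalization statistics are fitted on them; with fitted ``params``
    the rows (e.g. held-out subjects) are transformed only.

    The alpha:theta ratio is always *formed* from raw band powers (a
    ratio of already-dB-scaled values would be ill-defined near 0 dB).
    In the decibel scenario ``ratio_domain="log"`` (default) then
    expresses it in the log domain, ``10*log10(alpha/theta)`` — the dB
    difference of the two bands — keeping every feature's noise model in
    the same (additive, decibel) family; ``"linear"`` keeps the plain
    quotient. Outside the decibel scenario the quotient is always used.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if ratio_domain not in ("log", "linear"):
        raise ValueError(f"ratio_domain must be 'log' or 'linear', got {ratio_domain!r}")
    band_cols = [c for c in power_table.columns if c not in POWER_META]

    fitting = params is None
    if not fitting:
        ratio_domain = params.ratio_domain
        if params.scenario != scenario:
            raise ValueError(
                f"params fitted for scenario {params.scenario!r}, requested {scenario!r}"
            )
        if not params.fitted:
            raise ValueError("cannot transform with unfitted NormalizationParams")

    frame = _raw_feature_frame(power_table)
    feature_names = band_cols + ["alpha_theta_ratio"]

    if fitting:
        params = NormalizationParams(
            scenario=scenario, baseline_policy=baseline_policy,
            ratio_domain=ratio_domain, feature_names=feature_names,
        )
        if scenario == "decibel_plus_feature":
            params.db_baseline = fit_baseline_from_table(power_table, baseline_policy)

    if scenario == "decibel_plus_feature":
        if ratio_domain == "log":
            frame["alpha_theta_ratio"] = 10.0 * np.log10(
                frame["alpha_theta_ratio"].to_numpy()
            )
        for c in band_cols:
            frame[c] = db_normalize(frame[c].to_numpy(), params.db_baseline[c])

    if scenario in ("feature_only", "decibel_plus_feature"):
        if fitting:
            params.feat_mean = frame[feature_names].mean()
            sd = frame[feature_names].std(ddof=0)
            # constant columns have SD ~ 1e-16 x mean from rounding alone
            tiny = sd <= 1e-12 * (params.feat_mean.abs() + 1.0)
            if tiny.any():
                logger.warning(
                    "constant feature(s) %s: z-scoring with SD=1",
                    sd.index[tiny].tolist(),
                )
                sd[tiny] = 1.0
            params.feat_sd = sd
        frame[feature_names] = (frame[feature_names] - params.feat_mean) / params.feat_sd

    table = FeatureTable(
        data=frame[["subject", "group"] + feature_names].reset_index(drop=True),
        scenario=scenario,
        feature_names=feature_names,
    )
    return table, params


def build_features(
    epochsets: list[EpochSet],
    params: NormalizationParams | None = None,
    scenario: str = "decibel_plus_feature",
    baseline_policy: str = "first_5_epochs",
    bands: dict[str, tuple[float, float]] | None = None,
    ratio_domain: str = "log",
) -> tuple[FeatureTable, NormalizationParams]:
    """End-to-end: epochs -> raw band powers -> normalized feature table.

    See :func:`features_from_table`; this wrapper computes the raw power
    table first.
    """
    return features_from_table(
        band_power_table(epochsets, bands), params, scenario, baseline_policy,
        ratio_domain,
    )
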