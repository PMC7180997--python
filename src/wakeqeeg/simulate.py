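"""Synthetic sleep-EEG cohorts with controllable group spectral effects.

The generator emulates the statistical structure the downstream analysis
relies on, without any biophysical modelling:

* a Markov-chain hypnogram over {W, NREM, REM} at 4-s resolution whose
  transition matrix sets bout lengths and the stationary wake fraction;
* a 1/f-type broadband background (spectrally shaped Gaussian noise);
* five band-limited Gaussian components produced by passing white noise
  through the *same* Butterworth filter bank the feature extractor uses,
  each scaled to a per-band power in dB — so injected effects live
  exactly where the features look;
* a group effect: TBI subjects receive per-band dB offsets (default
  alpha attenuated by 3 dB, theta elevated by 3 dB);
* per-subject broadband gain jitter (one dB draw per subject), the
  nuisance that makes baseline normalization matter; and
* a fixed wake-vs-sleep spectral tilt so stages are not spectrally
  identical.

Everything is reproducible from ``(spec, spec.seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _signal

from .features import band_definitions, design_bandpass
from .io import (
    DEFAULT_BANDS,
    STAGES,
    Hypnogram,
    Recording,
    SubjectEntry,
    write_hypnogram,
    write_manifest,
    write_recording,
)

# Stage order for the transition matrix rows/columns.
STAGE_ORDER = list(STAGES)  # ["W", "NREM", "REM"]

#: Default 4-s-resolution stage-transition matrix (rows/cols W, NREM, REM).
#: Mean bout lengths: wake 8 min (120 scores), NREM ~8.7 min, REM 1.2 min;
#: stationary wake fraction ~0.45. With these bout statistics a 24-h
#: hypnogram yields on the order of 600 one-minute wake epochs per subject.
DEFAULT_TRANSITION = np.array(
    [
        [1 - 1 / 120, 0.95 / 120, 0.05 / 120],
        [0.5 / 130, 1 - 1 / 130, 0.5 / 130],
        [0.85 / 18, 0.15 / 18, 1 - 1 / 18],
    ]
)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    dB quantities are power dB (a +10 dB gain multiplies band power by 10).
    ``band_gains_db`` sets each band's baseline power relative to 1.0
    (theta), declining with frequency like the 1/f trend of real EEG.
    ``effect_db`` is added for TBI subjects only. ``amplitude_scale``
    calibrates the signal to a microvolt-like scale (RMS of a few tens of
    units, as in rodent EEG); raw band powers are therefore in arbitrary
    squared-amplitude units spanning roughly 30 to 900, which is what an
    un-normalized feature space actually looks like.

    Two kinds of per-subject nuisance are modelled: a broadband gain
    drawn once per subject (``subject_gain_sd_db`` — amplifier gain and
    electrode impedance differences, spectrally flat) and per-band gain
    offsets drawn once per subject (``subject_band_sd_db`` — differences
    in spectral shape from electrode placement and anatomy). The first is
    exactly what a log-power transform turns into a harmless additive
    constant; the second ensures no single feature, such as the
    alpha:theta ratio, is trivially invariant to all between-subject
    variation.

    ``band_fluct_sd_db``/``band_fluct_tau_min`` control the slow
    within-subject drift of each band's power (an AR(1) log-gain process
    at scoring resolution): real band power is not stationary over a
    recording — arousal and behavioural state move it by several dB on a
    minutes timescale — and without this drift every per-epoch feature
    would be unrealistically noise-free.

    ``artifacts`` models wake-epoch contamination as independent per-score
    power bursts confined to a subset of bands: by default *movement*
    artifacts (head motion — large low-frequency deflections hitting
    theta/alpha) and *EMG bleed* (muscle activity contaminating the
    sigma/beta/gamma range, the classic confound of 30-35 Hz EEG in
    behaving rodents). Each event draws one ``N(db, sd_db)`` magnitude
    applied to all of its bands during that 4-s score, during the listed
    stages only. The analysis pipeline performs no artifact rejection, so
    these heavy-tailed multiplicative bursts propagate into the raw
    features — the situation a logarithmic (decibel) representation is
    designed to tame.
    """

    n_sham: int = 5
    n_tbi: int = 4
    duration_h: float = 24.0
    fs: float = 256.0
    background_slope: float = 1.0
    background_rms: float = 0.1
    amplitude_scale: float = 30.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    # steep 1/f-type power decline across band centers (5.75 -> 32.5 Hz);
    # in real rodent EEG theta power exceeds gamma power by ~25 dB
    band_gains_db: dict[str, float] = field(
        default_factory=lambda: {
            "theta": 0.0,
            "alpha": -7.0,
            "sigma": -13.0,
            "beta": -18.0,
            "gamma": -25.0,
        }
    )
    effect_db: dict[str, float] = field(
        default_factory=lambda: {"alpha": -3.0, "theta": 3.0}
    )
    subject_gain_sd_db: float = 1.5
    subject_band_sd_db: float = 0.0
    band_fluct_sd_db: float = 2.0
    band_fluct_tau_min: float = 4.0
    artifacts: dict[str, dict] = field(
        default_factory=lambda: {
            "movement": {
                "rate": 0.08, "bands": ("theta", "alpha"),
                "db": 12.0, "sd_db": 3.0, "stages": ("W",),
            },
            "emg": {
                "rate": 0.15, "bands": ("sigma", "beta", "gamma"),
                "db": 18.0, "sd_db": 3.0, "stages": ("W",),
            },
        }
    )
    wake_tilt_db: dict[str, float] = field(
        default_factory=lambda: {"theta": -2.0, "beta": 1.5, "gamma": 1.5}
    )
    stage_transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION.copy()
    )
    score_epoch_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sham < 1 or self.n_tbi < 1:
            raise ValueError("need at least one subject per group")
        if not self.duration_h > 0:
            raise ValueError("duration_h must be positive")
        if self.subject_gain_sd_db < 0:
            raise ValueError("subject_gain_sd_db must be >= 0")
        if self.band_fluct_sd_db < 0:
            raise ValueError("band_fluct_sd_db must be >= 0")
        if self.subject_band_sd_db < 0:
            raise ValueError("subject_band_sd_db must be >= 0")
        for name, a in self.artifacts.items():
            if not 0 <= a.get("rate", 0.0) < 1:
                raise ValueError(f"artifact {name!r}: rate must be in [0, 1)")
        self.stage_transition = np.asarray(self.stage_transition, dtype=float)
        validate_transition(self.stage_transition)

    @property
    def n_scores(self) -> int:
        return int(round(self.duration_h * 3600.0 / self.score_epoch_s))


def validate_transition(P: np.ndarray) -> None:
    if P.shape != (3, 3):
        raise ValueError("stage_transition must be 3x3 (W, NREM, REM)")
    if np.any(P < 0):
        raise ValueError("stage_transition entries must be non-negative")
    rowsums = P.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-9):
        raise ValueError(f"stage_transition rows must sum to 1, got {rowsums}")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigvec)."""
    validate_transition(P)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_hypnogram(
    spec: CohortSpec, rng: np.random.Generator, start_stage: str = "W"
) -> Hypnogram:
    """Sample a Markov-chain hypnogram of ``spec.duration_h`` hours.

    Over a long recording the realized wake fraction approaches the
    chain's stationary W probability (binomial-like sampling error,
    inflated by bout autocorrelation).
    """
    P = spec.stage_transition
    n = spec.n_scores
    cum = np.cumsum(P, axis=1)
    state = STAGE_ORDER.index(start_stage)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int8)
    for i in range(n):
        out[i] = state
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 2)  # guard against u == 1.0 edge
    stages = np.asarray(STAGE_ORDER, dtype="U4")[out]
    return Hypnogram(stages=stages, score_epoch_s=spec.score_epoch_s)


def _ar1_log_gain(
    n_scores: int, sd_db: float, tau_scores: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) dB-gain series at scoring resolution."""
    if sd_db == 0:
        return np.zeros(n_scores)
    phi = float(np.exp(-1.0 / tau_scores))
    innov_sd = sd_db * np.sqrt(1.0 - phi**2)
    x = np.empty(n_scores)
    x[0] = rng.normal(0.0, sd_db)
    eps = rng.normal(0.0, innov_sd, size=n_scores - 1)
    for i in range(1, n_scores):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _pink_noise(n: int, slope: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with power spectral density ~ 1/f**slope."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)  # normalized; only relative shape matters
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-slope / 2.0)
    shaped = np.fft.irfft(spectrum * shaping, n=n)
    return shaped / np.sqrt(np.mean(shaped**2))


def simulate_recording(
    spec: CohortSpec,
    hypnogram: Hypnogram,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sim",
    jitter_db: float | None = None,
) -> Recording:
    """Synthesize a recording consistent with a hypnogram.

    The per-subject broadband jitter is drawn once from
    ``N(0, subject_gain_sd_db)`` unless supplied explicitly, and scales
    the entire signal (background included) — exactly the nuisance that
    decibel baseline normalization is meant to remove. Each band-limited
    component is normalized to unit RMS per realization before scaling,
    so empirical band power tracks the configured dB gains closely.
    """
    if jitter_db is None:
        jitter_db = float(rng.normal(0.0, spec.subject_gain_sd_db))
    band_names = [b.name for b in band_definitions(spec.bands)]
    subject_band_db = dict(
        zip(band_names, rng.normal(0.0, spec.subject_band_sd_db, len(band_names)))
    )
    samples_per_score = int(round(hypnogram.score_epoch_s * spec.fs))
    n = len(hypnogram) * samples_per_score

    sig = spec.background_rms * _pink_noise(n, spec.background_slope, rng)
    wake_mask = np.repeat(hypnogram.stages == "W", samples_per_score)

    # artifact bursts: one magnitude per event, shared by the event's bands
    artifact_db_per_band: dict[str, np.ndarray] = {}
    for a in spec.artifacts.values():
        stage_ok = np.isin(hypnogram.stages, np.asarray(a.get("stages", STAGES)))
        events = (rng.random(len(hypnogram)) < a.get("rate", 0.0)) & stage_ok
        magnitudes = np.where(
            events, rng.normal(a["db"], a.get("sd_db", 0.0), len(hypnogram)), 0.0
        )
        for b in a["bands"]:
            artifact_db_per_band[b] = artifact_db_per_band.get(b, 0.0) + magnitudes

    tau_scores = spec.band_fluct_tau_min * 60.0 / hypnogram.score_epoch_s
    for band in band_definitions(spec.bands):
        sos = design_bandpass(band, spec.fs)
        comp = _signal.sosfiltfilt(sos, rng.standard_normal(n))
        comp = comp / np.sqrt(np.mean(comp**2))
        gain_db = spec.band_gains_db.get(band.name, 0.0) + subject_band_db[band.name]
        if group == "tbi":
            gain_db += spec.effect_db.get(band.name, 0.0)
        # slow within-subject drift of this band's power, per 4-s score
        score_db = _ar1_log_gain(
            len(hypnogram), spec.band_fluct_sd_db, tau_scores, rng
        )
        if band.name in artifact_db_per_band:
            score_db = score_db + artifact_db_per_band[band.name]
        db_t = gain_db + np.repeat(score_db, samples_per_score)
        tilt = spec.wake_tilt_db.get(band.name, 0.0)
        if tilt:
            db_t = np.where(wake_mask, db_t + tilt, db_t)
        sig = sig + comp * 10.0 ** (db_t / 20.0)

    sig *= spec.amplitude_scale * 10.0 ** (jitter_db / 20.0)
    return Recording(samples=sig, fs=spec.fs, subject_id=subject_id, group=group)


def _subject_ids(spec: CohortSpec) -> list[tuple[str, str]]:
    ids = [(f"sham{i+1:02d}", "sham") for i in range(spec.n_sham)]
    ids += [(f"tbi{i+1:02d}", "tbi") for i in range(spec.n_tbi)]
    return ids


def simulate_cohort(spec: CohortSpec) -> list[tuple[Recording, Hypnogram]]:
    """Simulate the full cohort in memory, reproducibly from ``spec.seed``.

    Each subject gets an independent substream spawned from the cohort
    seed, so the cohort is identical regardless of evaluation order.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_sham + spec.n_tbi)
    out = []
    for (sid, group), ss in zip(_subject_ids(spec), streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        hyp = simulate_hypnogram(spec, rng)
        rec = simulate_recording(spec, hyp, group, rng, subject_id=sid)
        out.append((rec, hyp))
    return out


def generate_cohort(spec: CohortSpec, outdir: str | Path) -> Path:
    """Write a full cohort (recordings, hypnograms, manifest) to ``outdir``.

    Returns the manifest path. Identical ``(spec, seed)`` produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec, hyp in simulate_cohort(spec):
        rec_path = write_recording(rec, outdir / f"{rec.subject_id}.f32")
        hyp_path = write_hypnogram(hyp, outdir / f"{rec.subject_id}.hyp")
        entries.append(
            SubjectEntry(
                subject_id=rec.subject_id,
                group=rec.group,
                recording=rec_path.name,
                hypnogram=hyp_path.name,
            )
        )
    return write_manifest(entries, outdir / "manifest.json")
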