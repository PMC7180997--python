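"""Domain types and file I/O for single-channel sleep EEG.

A *Recording* is a continuous single-channel EEG trace with its sampling
rate and subject provenance; a *Hypnogram* is the aligned sequence of 4-s
sleep/wake stage labels produced by sleep scoring.  Cohorts are described
by a JSON manifest with one entry per subject (id, group, recording path,
hypnogram path) so that signal files stay format-pure.

Two signal formats are supported:

* the package's native dialect — raw little-endian float32 samples in a
  ``.f32`` file plus a JSON sidecar (``<stem>.json``) holding the sampling
  rate and metadata; and
* EDF, read through :mod:`mne` when it is installed (EDF is the standard
  interchange format for sleep EEG, but nothing in this package requires
  it).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger("wakeqeeg")

STAGES = ("W", "NREM", "REM")
GROUPS = ("sham", "tbi")

#: theta/alpha/sigma/beta/gamma passbands in Hz. Delta (0.5-4 Hz) is a
#: classical band but is deliberately not part of the feature set; the gaps
#: between passbands (7.5-8, 12-13, 16-16.5, 25-30 Hz) are left uncovered.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.5),
    "alpha": (8.0, 12.0),
    "sigma": (13.0, 16.0),
    "beta": (16.5, 25.0),
    "gamma": (30.0, 35.0),
}

DELTA_BAND: tuple[float, float] = (0.5, 4.0)  # available, off by default

SCENARIOS = ("none", "feature_only", "decibel_plus_feature")
BASELINE_POLICIES = ("first_5_epochs", "first_epoch")


class FormatError(ValueError):
    """Unparsable or structurally invalid input file."""


class UnknownChannelError(KeyError):
    """Requested channel absent from the signal file."""


class PairingError(ValueError):
    """Recording and hypnogram durations are inconsistent."""


@dataclass
class Recording:
    """Continuous single-channel EEG with subject provenance.

    Parameters
    ----------
    samples : ndarray
        Amplitude series in arbitrary (microvolt-like) units.
    fs : float
        Sampling rate in Hz (nominally 256).
    subject_id : str
    group : str
        ``"sham"`` or ``"tbi"``.
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Hypnogram:
    """Ordered stage labels at a fixed scoring resolution (default 4 s)."""

    stages: np.ndarray
    score_epoch_s: float = 4.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="U4")
        bad = set(self.stages.tolist()) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels {sorted(bad)}; allowed: {STAGES}")
        if not self.score_epoch_s > 0:
            raise ValueError("score_epoch_s must be positive")

    def __len__(self) -> int:
        return int(self.stages.size)

    @property
    def duration_s(self) -> float:
        return self.stages.size * self.score_epoch_s

    def wake_fraction(self) -> float:
        if self.stages.size == 0:
            return float("nan")
        return float(np.mean(self.stages == "W"))


def check_pairing(rec: Recording, hyp: Hypnogram) -> None:
    """Reject a recording/hypnogram pair whose durations disagree.

    The hypnogram may be up to one scoring epoch longer than the recording
    (a trailing partial score is common); anything beyond that indicates a
    mismatched pair.
    """
    if hyp.duration_s > rec.duration_s + hyp.score_epoch_s:
        raise PairingError(
            f"hypnogram covers {hyp.duration_s:.0f}s but recording is only "
            f"{rec.duration_s:.0f}s for subject {rec.subject_id!r}"
        )


@dataclass
class RunConfig:
    """Configuration of one classification experiment."""

    epoch_length_min: int = 1
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    baseline_policy: str = "first_5_epochs"
    normalization_scenario: str = "decibel_plus_feature"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_length_min not in (1, 2, 4):
            raise ValueError("epoch_length_min must be 1, 2 or 4")
        if self.baseline_policy not in BASELINE_POLICIES:
            raise ValueError(f"baseline_policy must be one of {BASELINE_POLICIES}")
        if self.normalization_scenario not in SCENARIOS:
            raise ValueError(f"normalization_scenario must be one of {SCENARIOS}")
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r} has invalid edges ({lo}, {hi})")
        # 1/2/4 min are all whole multiples of the 4-s scoring resolution.
        if (self.epoch_length_min * 60) % 4 != 0:
            raise ValueError("epoch length must divide into whole 4-s scores")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "epoch_length_min": self.epoch_length_min,
            "bands": {k: list(v) for k, v in self.bands.items()},
            "baseline_policy": self.baseline_policy,
            "normalization_scenario": self.normalization_scenario,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Recording I/O


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording in the raw float32 + JSON sidecar dialect.

    ``path`` should end in ``.f32``; the sidecar is written next to it with
    a ``.json`` suffix. Returns the signal path.
    """
    path = Path(path)
    if path.suffix != ".f32":
        path = path.with_suffix(".f32")
    rec.samples.astype("<f4").tofile(path)
    sidecar = {
        "format": "wakeqeeg-raw-v1",
        "dtype": "<f4",
        "fs": rec.fs,
        "n_samples": int(rec.samples.size),
        "subject_id": rec.subject_id,
        "group": rec.group,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def _read_raw_recording(path: Path, subject_id: str | None, group: str | None) -> Recording:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path} for raw recording {path}")
    try:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        fs = float(meta["fs"])
        dtype = meta.get("dtype", "<f4")
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"unparsable sidecar {sidecar_path}: {exc}") from exc
    samples = np.fromfile(path, dtype=dtype).astype(float)
    n_expected = meta.get("n_samples")
    if n_expected is not None and samples.size != int(n_expected):
        raise FormatError(
            f"{path}: sidecar declares {n_expected} samples, file holds {samples.size}"
        )
    return Recording(
        samples=samples,
        fs=fs,
        subject_id=subject_id or meta.get("subject_id", path.stem),
        group=group or meta.get("group", "sham"),
    )


def _read_edf_recording(
    path: Path, channel: str | int, subject_id: str | None, group: str | None
) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is normally present
        raise FormatError("reading EDF requires the 'mne' package") from exc
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"unparsable EDF file {path}: {exc}") from exc
    names = raw.ch_names
    if not names:
        raise UnknownChannelError(f"{path} contains no channels")
    if isinstance(channel, int):
        if not 0 <= channel < len(names):
            raise UnknownChannelError(
                f"channel index {channel} out of range for {len(names)} channels"
            )
        name = names[channel]
    else:
        if channel not in names:
            raise UnknownChannelError(f"channel {channel!r} not in {names}")
        name = channel
    data = raw.get_data(picks=[name])[0]
    return Recording(
        samples=np.asarray(data, dtype=float),
        fs=float(raw.info["sfreq"]),
        subject_id=subject_id or path.stem,
        group=group or "sham",
    )


def read_recording(
    path: str | Path,
    channel: str | int = 0,
    subject_id: str | None = None,
    group: str | None = None,
) -> Recording:
    """Read a single channel of EEG from ``.f32``+sidecar or ``.edf``.

    The native raw dialect is single-channel; ``channel`` applies to EDF
    files, by name or 0-based index. ``subject_id``/``group`` override the
    sidecar metadata (EDF carries neither, so they default to the file stem
    and ``"sham"`` unless given).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf_recording(path, channel, subject_id, group)
    return _read_raw_recording(path, subject_id, group)


# ---------------------------------------------------------------------------
# Hypnogram I/O


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(hyp.stages.tolist()))
        if len(hyp):
            fh.write("\n")
    return path


def read_hypnogram(path: str | Path, score_epoch_s: float = 4.0) -> Hypnogram:
    """Read a one-stage-per-line text hypnogram (W/NREM/REM, case-insensitive).

    An optional single header line reading ``stage`` is skipped. An empty
    file yields an empty hypnogram (valid: zero wake epochs downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stages: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            if lineno == 1 and token.lower() in ("stage", "stages"):
                continue
            label = token.upper()
            if label not in STAGES:
                raise FormatError(
                    f"{path}:{lineno}: unknown stage label {token!r} "
                    f"(allowed: {', '.join(STAGES)})"
                )
            stages.append(label)
    return Hypnogram(stages=np.array(stages, dtype="U4"), score_epoch_s=score_epoch_s)


# ---------------------------------------------------------------------------
# Cohort manifest


@dataclass
class SubjectEntry:
    subject_id: str
    group: str
    recording: Path
    hypnogram: Path


def write_manifest(entries: Sequence[SubjectEntry], path: str | Path) -> Path:
    path = Path(path)
    base = path.parent
    data = {
        "format": "wakeqeeg-manifest-v1",
        "subjects": [
            {
                "id": e.subject_id,
                "group": e.group,
                "recording": str(Path(e.recording).relative_to(base))
                if Path(e.recording).is_absolute()
                else str(e.recording),
                "hypnogram": str(Path(e.hypnogram).relative_to(base))
                if Path(e.hypnogram).is_absolute()
                else str(e.hypnogram),
            }
            for e in entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
    return path


def read_manifest(path: str | Path) -> list[SubjectEntry]:
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
        subjects = data["subjects"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"unparsable manifest {path}: {exc}") from exc
    entries = []
    for s in subjects:
        if s["group"] not in GROUPS:
            raise FormatError(f"manifest subject {s.get('id')}: bad group {s['group']!r}")
        entries.append(
            SubjectEntry(
                subject_id=s["id"],
                group=s["group"],
                recording=path.parent / s["recording"],
                hypnogram=path.parent / s["hypnogram"],
            )
        )
    return entries


def load_cohort(manifest_path: str | Path) -> list[tuple[Recording, Hypnogram]]:
    """Load every subject in a manifest as (Recording, Hypnogram) pairs.

    Each pair is duration-checked; a mismatch raises :class:`PairingError`.
    """
    pairs = []
    for entry in read_manifest(manifest_path):
        rec = read_recording(entry.recording, subject_id=entry.subject_id, group=entry.group)
        hyp = read_hypnogram(entry.hypnogram)
        check_pairing(rec, hyp)
        pairs.append((rec, hyp))
    return pairs
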