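"""Extraction of non-overlapping wake epochs from scored recordings.

The hypnogram assigns a stage to every consecutive 4-s score. A *wake
epoch* of length 1, 2 or 4 minutes is a contiguous stretch of signal that
covers only W-scored intervals. Extraction is a greedy left-to-right scan
over the score sequence: a run of k consecutive W scores (k = 15 per
minute of epoch length) yields one epoch and the scan resumes immediately
after it; any non-W score resets the current run, so epochs never
straddle even a single sleep score. Within a maximal W run the packing is
run-aligned — epochs start at the run's first score — which makes the
per-subject epoch counts deterministic. Returned segments are raw,
unfiltered signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Hypnogram, Recording, check_pairing


@dataclass
class EpochSet:
    """Wake epochs of one subject at one epoch length.

    ``epochs`` is an (n_epochs, epoch_samples) array of raw signal;
    ``start_offsets`` holds the 0-based sample index of each epoch
    (intervals are half-open ``[start, start + epoch_samples)``).
    """

    epochs: np.ndarray
    epoch_length_s: float
    fs: float
    subject_id: str
    group: str
    start_offsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.start_offsets = np.asarray(self.start_offsets, dtype=int)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must be a 2-D (n_epochs, n_samples) array")
        expected = int(round(self.epoch_length_s * self.fs))
        if self.epochs.shape[0] and self.epochs.shape[1] != expected:
            raise ValueError(
                f"epochs have {self.epochs.shape[1]} samples, expected {expected}"
            )
        if self.start_offsets.size != self.epochs.shape[0]:
            raise ValueError("start_offsets length must equal epoch count")

    def __len__(self) -> int:
        return int(self.epochs.shape[0])


def wake_run_starts(stages: np.ndarray, scores_per_epoch: int) -> list[int]:
    """Score indices at which greedy run-aligned epochs begin.

    Equivalent to enumerating maximal W runs and packing each with
    ``floor(run_length / scores_per_epoch)`` consecutive epochs from the
    run's first score.
    """
    starts: list[int] = []
    run = 0
    for i, stage in enumerate(stages):
        if stage == "W":
            run += 1
            if run == scores_per_epoch:
                starts.append(i - scores_per_epoch + 1)
                run = 0
        else:
            run = 0
    return starts


def extract_wake_epochs(
    rec: Recording, hyp: Hypnogram, epoch_length_min: int = 1
) -> EpochSet:
    """Greedy extraction of non-overlapping wake epochs.

    Parameters
    ----------
    rec, hyp : paired recording and hypnogram (duration-checked here).
    epoch_length_min : epoch length in minutes; must be a whole multiple
        of the hypnogram's scoring resolution.
    """
    check_pairing(rec, hyp)
    epoch_s = epoch_length_min * 60.0
    if epoch_s % hyp.score_epoch_s != 0:
        raise ValueError(
            f"epoch length {epoch_s}s is not a multiple of the "
            f"{hyp.score_epoch_s}s scoring resolution"
        )
    scores_per_epoch = int(epoch_s // hyp.score_epoch_s)
    samples_per_score = int(round(hyp.score_epoch_s * rec.fs))
    epoch_samples = scores_per_epoch * samples_per_score

    starts = wake_run_starts(hyp.stages, scores_per_epoch)
    offsets = []
    segments = []
    for s in starts:
        off = s * samples_per_score
        if off + epoch_samples <= rec.samples.size:
            offsets.append(off)
            segments.append(rec.samples[off : off + epoch_samples])
    epochs = (
        np.stack(segments) if segments else np.empty((0, epoch_samples), dtype=float)
    )
    return EpochSet(
        epochs=epochs,
        epoch_length_s=epoch_s,
        fs=rec.fs,
        subject_id=rec.subject_id,
        group=rec.group,
        start_offsets=np.asarray(offsets, dtype=int),
    )
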