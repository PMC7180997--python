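"""Leave-two-subjects-out cross-validation and scenario/epoch-length sweeps.

Every fold holds out exactly one sham and one TBI subject; the exhaustive
pairing of a 5-sham/4-TBI cohort gives 20 folds. Within a fold, all
normalization statistics (decibel baselines, feature mean/SD) are fitted
on the seven training subjects only and applied unchanged to the two
held-out subjects, whose pooled epochs are scored per-epoch. Models
sharing a fold share the same transformed features, so model comparisons
isolate the classifier, not the preprocessing.

The expensive steps (epoch extraction, band-pass filtering) are done once
per epoch length and cached as raw power tables; folds and scenarios then
reuse them, which is what keeps a full sweep desk-scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import CnnClassifier
from .epoching import EpochSet, extract_wake_epochs
from .features import (
    NormalizationParams,
    band_power_table,
    features_from_table,
    fit_baseline_from_table,
)
from .io import Hypnogram, Recording, RunConfig, load_cohort
from .models import (
    ModelSpec,
    accuracy,
    predict,
    train_rule_based,
    windowed_tensor,
)

logger = logging.getLogger("wakeqeeg")


@dataclass(frozen=True)
class CVFold:
    """One leave-two-subjects-out trial."""

    fold_index: int
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]  # (one sham, one tbi)


def make_folds(sham_ids: list[str], tbi_ids: list[str]) -> list[CVFold]:
    """Exhaustive one-sham x one-TBI held-out pairs, lexicographic order.

    With 5 sham and 4 TBI subjects this yields the full set of 20 trials;
    each sham appears in exactly ``len(tbi_ids)`` folds and vice versa.
    """
    if not sham_ids or not tbi_ids:
        raise ValueError("both groups must be non-empty")
    if len(set(sham_ids) & set(tbi_ids)) > 0:
        raise ValueError("a subject cannot belong to both groups")
    folds = []
    for i, (s, t) in enumerate(itertools.product(sorted(sham_ids), sorted(tbi_ids))):
        train = tuple(x for x in sorted(sham_ids) + sorted(tbi_ids) if x not in (s, t))
        folds.append(CVFold(fold_index=i, train_subjects=train, test_subjects=(s, t)))
    return folds


@dataclass
class CVReport:
    """Long-format per-fold results plus aggregation helpers.

    ``results`` has one row per (model, scenario, epoch_length, fold) with
    the pooled per-epoch test accuracy in percent and per-subject
    accuracies for reference.
    """

    results: pd.DataFrame
    config: RunConfig | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean accuracy and cross-fold variance per model/scenario/length.

        The variance is the population variance (divide by the number of
        folds) of the %-valued fold accuracies.
        """
        grouped = self.results.groupby(["model", "scenario", "epoch_length_min"])
        out = grouped["accuracy_pct"].agg(
            mean_accuracy_pct="mean",
            variance_pct=lambda a: float(np.var(a)),
            n_folds="count",
        )
        return out.reset_index()


def variance_summary(report: CVReport) -> pd.DataFrame:
    """Cross-fold population variance of accuracy (%-scale) per model."""
    counts = report.results.groupby("model")["accuracy_pct"].count()
    if (counts < 2).any():
        raise ValueError("cross-fold variance is undefined with fewer than 2 folds")
    return (
        report.results.groupby("model")["accuracy_pct"]
        .agg(variance_pct=lambda a: float(np.var(a)))
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Experiment runner


def _prepare_tables(
    cohort: list[tuple[Recording, Hypnogram]],
    epoch_lengths: list[int],
    bands,
    need_windows: bool,
) -> dict[int, dict]:
    """Per-epoch-length caches: epoch sets, raw power tables, window tensors."""
    cache: dict[int, dict] = {}
    for length in epoch_lengths:
        epochsets: list[EpochSet] = [
            extract_wake_epochs(rec, hyp, length) for rec, hyp in cohort
        ]
        empty = [es.subject_id for es in epochsets if len(es) == 0]
        if empty:
            raise ValueError(
                f"subjects {empty} have no wake epochs at {length} min"
            )
        powers = band_power_table(epochsets, bands)
        windows = None
        if need_windows:
            windows = {es.subject_id: windowed_tensor(es, bands) for es in epochsets}
        cache[length] = {
            "epochsets": {es.subject_id: es for es in epochsets},
            "powers": powers,
            "windows": windows,
        }
    return cache


def _cnn_fold_accuracy(
    window_cache: dict[str, np.ndarray],
    groups: dict[str, str],
    fold: CVFold,
    db_baseline: dict[str, float],
    band_names: list[str],
    seed: int,
    cnn_kwargs: dict,
) -> tuple[float, dict[str, float]]:
    base = np.array([db_baseline[n] for n in band_names])

    def to_db(subjects):
        X, y = [], []
        for sid in subjects:
            t = window_cache[sid]
            X.append(10.0 * np.log10(t / base))
            y.append(np.full(t.shape[0], 1 if groups[sid] == "tbi" else 0))
        return np.concatenate(X), np.concatenate(y)

    Xtr, ytr = to_db(fold.train_subjects)
    net = CnnClassifier(seed=seed + fold.fold_index, **cnn_kwargs)
    net.fit(Xtr, ytr)
    per_subject = {}
    correct = total = 0
    for sid in fold.test_subjects:
        Xte, yte = to_db([sid])
        pred = net.predict(Xte)
        per_subject[sid] = accuracy(pred, yte)
        correct += int(np.sum(pred == yte))
        total += yte.size
    return correct / total, per_subject


def run_experiment(
    config: RunConfig,
    manifest: str | Path | list[tuple[Recording, Hypnogram]],
    models: list[ModelSpec],
    scenarios: list[str] | None = None,
    epoch_lengths: list[int] | None = None,
    cnn_kwargs: dict | None = None,
    fold_subset: list[int] | None = None,
) -> CVReport:
    """Run the full leave-two-subjects-out protocol.

    Parameters
    ----------
    config : RunConfig
        Supplies the bands, baseline policy, seed, and the default
        scenario/epoch length when no sweep lists are given.
    manifest : path or in-memory cohort
        A cohort manifest path or a list of (Recording, Hypnogram) pairs.
    models : list of ModelSpec
        Any of dt/rf/svm/knn3/knn5/knn7/nn/cnn. The cnn entry uses the
        windowed decibel front end regardless of scenario (its features
        are always baseline-normalized); rule-based models follow the
        scenario.
    scenarios, epoch_lengths : optional sweep lists
        Default to the single values in ``config``.
    fold_subset : optional list of fold indices
        Restrict the run to these folds (e.g. a reduced subset for the
        compute-heavy convolutional model); default is all folds.

    Returns a :class:`CVReport` whose ``results`` frame has
    |models| x |scenarios| x |epoch lengths| x n_folds rows.
    """
    cohort = manifest if isinstance(manifest, list) else load_cohort(manifest)
    scenarios = scenarios or [config.normalization_scenario]
    epoch_lengths = epoch_lengths or [config.epoch_length_min]
    cnn_kwargs = cnn_kwargs or {}

    groups = {rec.subject_id: rec.group for rec, _ in cohort}
    sham_ids = [s for s, g in groups.items() if g == "sham"]
    tbi_ids = [s for s, g in groups.items() if g == "tbi"]
    folds = make_folds(sham_ids, tbi_ids)
    if fold_subset is not None:
        folds = [f for f in folds if f.fold_index in set(fold_subset)]
        if not folds:
            raise ValueError("fold_subset selected no folds")

    need_windows = any(m.name == "cnn" for m in models)
    cache = _prepare_tables(cohort, epoch_lengths, config.bands, need_windows)
    band_names = list(config.bands.keys())

    rows = []
    for length in epoch_lengths:
        powers = cache[length]["powers"]
        for fold in folds:
            train_mask = powers["subject"].isin(fold.train_subjects)
            train_powers = powers[train_mask]
            test_powers = powers[powers["subject"].isin(fold.test_subjects)]

            # decibel baseline shared by the cnn front end and the
            # decibel_plus_feature scenario; fitted on training subjects only
            db_baseline = fit_baseline_from_table(train_powers, config.baseline_policy)

            scenario_tables: dict[str, tuple] = {}
            for scenario in scenarios:
                train_table, params = features_from_table(
                    train_powers, None, scenario, config.baseline_policy
                )
                test_table, _ = features_from_table(
                    test_powers, params, scenario, config.baseline_policy
                )
                scenario_tables[scenario] = (train_table, test_table, params)

            for model in models:
                if model.name == "cnn":
                    acc, per_subject = _cnn_fold_accuracy(
                        cache[length]["windows"], groups, fold, db_baseline,
                        band_names, config.seed + model.seed, cnn_kwargs,
                    )
                    for scenario in scenarios:
                        rows.append(
                            _result_row(model, scenario, length, fold, acc, per_subject)
                        )
                    continue
                for scenario in scenarios:
                    train_table, test_table, _ = scenario_tables[scenario]
                    spec = ModelSpec(
                        model.name, model.hyperparameters,
                        seed=config.seed + model.seed + fold.fold_index,
                    )
                    fitted = train_rule_based(spec, train_table)
                    pred, _scores = predict(fitted, test_table)
                    acc = accuracy(pred, test_table.y)
                    per_subject = {
                        sid: accuracy(
                            pred[test_table.subjects == sid],
                            test_table.y[test_table.subjects == sid],
                        )
                        for sid in fold.test_subjects
                    }
                    rows.append(
                        _result_row(model, scenario, length, fold, acc, per_subject)
                    )
            logger.debug("fold %d at %d min done", fold.fold_index, length)

    results = pd.DataFrame(rows)
    return CVReport(results=results, config=config)


def _result_row(model, scenario, length, fold, acc, per_subject) -> dict:
    row = {
        "model": model.name,
        "scenario": scenario,
        "epoch_length_min": length,
        "fold": fold.fold_index,
        "test_sham": fold.test_subjects[0],
        "test_tbi": fold.test_subjects[1],
        "accuracy_pct": 100.0 * acc,
    }
    for sid, a in per_subject.items():
        row[f"accuracy_{'sham' if sid == fold.test_subjects[0] else 'tbi'}_pct"] = (
            100.0 * a
        )
    return row
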