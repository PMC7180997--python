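"""Synthetic cohort generator: hypnogram chain, spectral calibration,
effect injection, determinism."""

import numpy as np
import pytest
from scipy import signal as _signal

from wakeqeeg import (
    CohortSpec,
    generate_cohort,
    load_cohort,
    simulate_cohort,
    simulate_hypnogram,
    simulate_recording,
    stationary_distribution,
)
from wakeqeeg.epoching import wake_run_starts
from wakeqeeg.io import DEFAULT_BANDS, Hypnogram
from wakeqeeg.simulate import DEFAULT_TRANSITION

QUIET = dict(subject_gain_sd_db=0.0, band_fluct_sd_db=0.0, artifacts={})


def periodogram_band_power(x, fs, band):
    """Oracle band power: integrate the periodogram over the passband."""
    f, pxx = _signal.periodogram(x, fs=fs)
    lo, hi = band
    return float(np.trapezoid(pxx[(f >= lo) & (f <= hi)], f[(f >= lo) & (f <= hi)]))


class TestHypnogram:
    def test_identity_transition_is_absorbing(self):
        spec = CohortSpec(duration_h=0.5, stage_transition=np.eye(3), seed=0)
        hyp = simulate_hypnogram(spec, np.random.default_rng(0), start_stage="W")
        assert (hyp.stages == "W").all()

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(stage_transition=np.full((3, 3), 0.5))

    def test_wake_fraction_matches_stationary_probability(self):
        # iid rows: stationary distribution equals the common row
        P = np.tile([0.5, 0.3, 0.2], (3, 1))
        np.testing.assert_allclose(stationary_distribution(P), [0.5, 0.3, 0.2], atol=1e-12)
        spec = CohortSpec(duration_h=24.0, stage_transition=P, seed=0)
        hyp = simulate_hypnogram(spec, np.random.default_rng(42))
        n = len(hyp)
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(hyp.wake_fraction() - 0.5) < 3 * se

    def test_default_chain_gives_table_scale_epoch_counts(self):
        # 24-h hypnograms from the default bout structure must land in the
        # observed per-mouse range of ~200-920 one-minute wake epochs,
        # with counts decreasing as epoch length grows
        spec = CohortSpec(duration_h=24.0, seed=0)
        for s in range(5):
            hyp = simulate_hypnogram(spec, np.random.default_rng(100 + s))
            c1 = len(wake_run_starts(hyp.stages, 15))
            c2 = len(wake_run_starts(hyp.stages, 30))
            c4 = len(wake_run_starts(hyp.stages, 60))
            assert 200 <= c1 <= 920
            assert c4 <= c2 <= c1


class TestRecording:
    def test_sample_count(self):
        spec = CohortSpec(duration_h=1.0, seed=0)
        hyp = Hypnogram(stages=np.array(["W"] * 15))  # 60 s
        rec = simulate_recording(spec, hyp, "sham", np.random.default_rng(0))
        assert rec.samples.size == 15360  # 256 Hz x 60 s

    def test_band_power_responds_log_linearly_to_gain(self):
        # 1 dB of configured gain moves measured alpha band power by
        # 1 dB (slope within 10%), against a periodogram oracle
        hyp = Hypnogram(stages=np.array(["W"] * 150))  # 10 min
        measured = []
        gains = [-6.0, -3.0, 0.0, 3.0, 6.0]
        for g in gains:
            spec = CohortSpec(duration_h=1.0, seed=0, **QUIET)
            spec.band_gains_db = dict(spec.band_gains_db)
            spec.band_gains_db["alpha"] = spec.band_gains_db["alpha"] + g
            rec = simulate_recording(spec, hyp, "sham", np.random.default_rng(7))
            measured.append(
                10 * np.log10(periodogram_band_power(rec.samples, 256.0, DEFAULT_BANDS["alpha"]))
            )
        slope = np.polyfit(gains, measured, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.10)

    def test_alpha_attenuation_recovers_configured_ratio(self):
        # -3 dB alpha effect -> TBI/sham mean alpha power ratio ~ 0.501
        from wakeqeeg.epoching import extract_wake_epochs
        from wakeqeeg.features import band_power_table

        spec = CohortSpec(
            duration_h=2.0, seed=5, effect_db={"alpha": -3.0}, **QUIET
        )
        cohort = simulate_cohort(spec)
        epochsets = [extract_wake_epochs(r, h, 1) for r, h in cohort]
        table = band_power_table(epochsets)
        assert len(table) >= 100
        means = table.groupby("group")["alpha"].mean()
        ratio = means["tbi"] / means["sham"]
        assert ratio == pytest.approx(10 ** -0.3, rel=0.15)

    def test_zero_effect_groups_exchangeable(self):
        from scipy import stats

        from wakeqeeg.epoching import extract_wake_epochs
        from wakeqeeg.features import band_power_table

        spec = CohortSpec(
            n_sham=2, n_tbi=2, duration_h=1.0, seed=8, effect_db={}, **QUIET
        )
        epochsets = [extract_wake_epochs(r, h, 1) for r, h in simulate_cohort(spec)]
        table = band_power_table(epochsets)
        a = table.loc[table.group == "sham", "alpha"]
        b = table.loc[table.group == "tbi", "alpha"]
        assert min(len(a), len(b)) >= 25
        assert stats.ttest_ind(np.log(a), np.log(b)).pvalue > 0.01

    def test_effect_confined_to_specified_bands(self):
        from wakeqeeg.epoching import extract_wake_epochs
        from wakeqeeg.features import band_power_table

        spec = CohortSpec(
            duration_h=2.0, seed=4, effect_db={"alpha": -6.0}, **QUIET
        )
        epochsets = [extract_wake_epochs(r, h, 1) for r, h in simulate_cohort(spec)]
        table = band_power_table(epochsets)
        assert len(table) >= 200
        means = table.groupby("group").mean(numeric_only=True)
        for band in ("theta", "sigma", "beta", "gamma"):
            ratio_db = 10 * np.log10(means.loc["tbi", band] / means.loc["sham", band])
            assert abs(ratio_db) < 0.5, band


class TestCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        spec = CohortSpec(n_sham=1, n_tbi=1, duration_h=0.1, seed=77)
        m1 = generate_cohort(spec, tmp_path / "a")
        m2 = generate_cohort(spec, tmp_path / "b")
        for f1 in sorted(m1.parent.iterdir()):
            f2 = m2.parent / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_round_trip_through_manifest(self, tmp_path):
        spec = CohortSpec(n_sham=1, n_tbi=1, duration_h=0.1, seed=1)
        manifest = generate_cohort(spec, tmp_path)
        pairs = load_cohort(manifest)
        assert [(r.subject_id, r.group) for r, _ in pairs] == [
            ("sham01", "sham"),
            ("tbi01", "tbi"),
        ]
        in_memory = simulate_cohort(spec)
        for (r_disk, h_disk), (r_mem, h_mem) in zip(pairs, in_memory):
            np.testing.assert_allclose(
                r_disk.samples, r_mem.samples, rtol=1e-6, atol=1e-5
            )
            assert h_disk.stages.tolist() == h_mem.stages.tolist()

    def test_default_cohort_has_nine_subjects(self):
        spec = CohortSpec()
        assert spec.n_sham + spec.n_tbi == 9

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_sham=0)
        with pytest.raises(ValueError):
            CohortSpec(duration_h=-1)
        with pytest.raises(ValueError):
            CohortSpec(subject_gain_sd_db=-0.1)
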