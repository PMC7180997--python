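"""Spectral feature primitives: DFT power, dB scaling, filter bank,
baseline fitting and the three normalization scenarios."""

import numpy as np
import pandas as pd
import pytest

from wakeqeeg.features import (
    BandDefinition,
    FeatureTable,
    band_definitions,
    bandpass,
    build_features,
    db_normalize,
    features_from_table,
    fit_baseline_from_table,
    mean_power,
)
from wakeqeeg.io import DEFAULT_BANDS

FS = 256.0
ALPHA = BandDefinition("alpha", *DEFAULT_BANDS["alpha"])
GAMMA = BandDefinition("gamma", *DEFAULT_BANDS["gamma"])


class TestMeanPower:
    def test_equals_time_domain_mean_square_for_random_segments(self, rng):
        # Parseval: the DFT power estimate is exactly the mean squared
        # amplitude, for any segment length (odd, even, prime)
        for _ in range(100):
            n = int(rng.integers(2, 4000))
            x = rng.normal(scale=rng.uniform(0.1, 50), size=n)
            assert mean_power(x) == pytest.approx(np.mean(x**2), rel=1e-9)

    def test_unit_sinusoid_at_bin_frequency_is_half(self):
        t = np.arange(15360) / FS
        x = np.sin(2 * np.pi * 10.0 * t)  # 10 Hz is bin-centered for 60 s
        assert mean_power(x) == pytest.approx(0.5, rel=1e-9)

    def test_constant_signal_gives_dc_power(self):
        assert mean_power(np.full(1000, 3.0)) == pytest.approx(9.0, rel=1e-12)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            mean_power(np.empty(0))


class TestDbNormalize:
    def test_identities(self):
        assert db_normalize(1.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert db_normalize(10.0, 1.0) == pytest.approx(10.0, rel=1e-12)
        assert db_normalize(0.5, 1.0) == pytest.approx(-3.0103, abs=1e-4)

    def test_monotone_in_activity(self, rng):
        acts = np.sort(rng.uniform(0.01, 100, size=50))
        vals = db_normalize(acts, 7.3)
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("activity,baseline", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_non_positive_inputs_rejected(self, activity, baseline):
        with pytest.raises(ValueError):
            db_normalize(activity, baseline)


class TestBandpass:
    def test_in_band_sinusoid_passes_with_unity_gain(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, ALPHA, FS)
        assert np.sqrt(np.mean(y**2)) == pytest.approx(np.sqrt(np.mean(x**2)), rel=0.05)

    def test_out_of_band_sinusoid_is_rejected(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, GAMMA, FS)
        assert mean_power(y) < 0.01 * mean_power(x)

    def test_zero_in_zero_out(self):
        y = bandpass(np.zeros(1000), ALPHA, FS)
        np.testing.assert_allclose(y, 0.0)

    def test_band_edge_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), BandDefinition("too_high", 30.0, 40.0), fs=64.0)

    def test_band_power_slope_two_db_per_amplitude_db(self):
        # power of a pure in-band tone scales as A^2: +6.02 dB per
        # amplitude doubling
        t = np.arange(int(60 * FS)) / FS
        powers = []
        for amp in (1.0, 2.0, 4.0):
            y = bandpass(amp * np.sin(2 * np.pi * 10.0 * t), ALPHA, FS)
            powers.append(mean_power(y))
        ratios_db = 10 * np.diff(np.log10(powers))
        np.testing.assert_allclose(ratios_db, 6.02, atol=0.1)


def power_frame(rows):
    return pd.DataFrame(
        rows, columns=["subject", "group", "epoch_index"] + list(DEFAULT_BANDS)
    )


class TestFitBaseline:
    def test_single_subject_first_epoch_policy(self):
        table = power_frame([("a", "sham", 0, 1.0, 2.0, 3.0, 4.0, 5.0)])
        base = fit_baseline_from_table(table, "first_epoch")
        assert base == {"theta": 1.0, "alpha": 2.0, "sigma": 3.0, "beta": 4.0, "gamma": 5.0}

    def test_pooled_mean_across_two_subjects(self):
        rows = [("a", "sham", i, 1.0, 1.0, 1.0, 1.0, 1.0) for i in range(5)]
        rows += [("b", "tbi", i, 3.0, 3.0, 3.0, 3.0, 3.0) for i in range(5)]
        base = fit_baseline_from_table(power_frame(rows), "first_5_epochs")
        assert all(v == pytest.approx(2.0) for v in base.values())

    def test_matches_brute_force_pooled_mean(self, rng):
        rows = []
        for sid in "abcd":
            for i in range(int(rng.integers(5, 12))):
                rows.append((sid, "sham", i, *rng.uniform(0.1, 10, size=5)))
        table = power_frame(rows)
        base = fit_baseline_from_table(table, "first_5_epochs")
        selected = table.groupby("subject", sort=False).head(5)
        for band in DEFAULT_BANDS:
            assert base[band] == pytest.approx(selected[band].mean(), rel=1e-12)

    def test_subject_with_too_few_epochs_is_named(self):
        rows = [("short", "sham", i, 1, 1, 1, 1, 1) for i in range(3)]
        with pytest.raises(ValueError, match="short"):
            fit_baseline_from_table(power_frame(rows), "first_5_epochs")


class TestScenarios:
    @staticmethod
    def random_table(rng, subjects=("a", "b", "c"), n=10):
        rows = []
        for s in subjects:
            group = "tbi" if s in ("c", "d") else "sham"
            for i in range(n):
                rows.append((s, group, i, *rng.uniform(0.5, 20, size=5)))
        return power_frame(rows)

    def test_training_rows_are_zero_mean_unit_sd(self, rng):
        table = self.random_table(rng)
        for scenario in ("feature_only", "decibel_plus_feature"):
            ft, _ = features_from_table(table, None, scenario)
            X = ft.X
            np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)
            np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-9)

    def test_scenario_none_returns_raw_powers_and_quotient_ratio(self, rng):
        table = self.random_table(rng)
        ft, _ = features_from_table(table, None, "none")
        np.testing.assert_allclose(ft.data["theta"], table["theta"])
        np.testing.assert_allclose(
            ft.data["alpha_theta_ratio"], table["alpha"] / table["theta"]
        )

    def test_transforming_with_unfitted_params_rejected(self, rng):
        from wakeqeeg.features import NormalizationParams

        table = self.random_table(rng)
        with pytest.raises(ValueError, match="unfitted"):
            features_from_table(
                table, NormalizationParams(scenario="feature_only"), "feature_only"
            )

    def test_fitted_params_do_not_depend_on_test_rows(self, rng):
        train = self.random_table(rng, subjects=("a", "b", "c", "d"))
        test1 = self.random_table(rng, subjects=("e",))
        test2 = self.random_table(rng, subjects=("e",))  # different draw
        _, p0 = features_from_table(train, None, "decibel_plus_feature")
        out1, _ = features_from_table(test1, p0, "decibel_plus_feature")
        _, p1 = features_from_table(train, None, "decibel_plus_feature")
        assert p0.db_baseline == p1.db_baseline
        pd.testing.assert_series_equal(p0.feat_mean, p1.feat_mean)
        # transforming different test sets leaves the params untouched
        out2, _ = features_from_table(test2, p0, "decibel_plus_feature")
        assert p0.db_baseline == p1.db_baseline
        assert not out1.data.equals(out2.data)

    def test_constant_feature_zscored_with_unit_sd(self, rng, caplog):
        table = self.random_table(rng)
        table["sigma"] = 4.2  # degenerate constant feature
        with caplog.at_level("WARNING", logger="wakeqeeg"):
            ft, params = features_from_table(table, None, "feature_only")
        assert "sigma" in caplog.text
        assert params.feat_sd["sigma"] == 1.0
        assert np.isfinite(ft.X).all()

    def test_log_ratio_in_decibel_scenario_is_db_difference(self, rng):
        table = self.random_table(rng)
        ft, params = features_from_table(table, None, "decibel_plus_feature")
        raw_db_diff = 10 * np.log10(table["alpha"] / table["theta"])
        expected = (raw_db_diff - raw_db_diff.mean()) / raw_db_diff.std(ddof=0)
        np.testing.assert_allclose(ft.data["alpha_theta_ratio"], expected, atol=1e-9)

    def test_feature_table_rejects_missing_values(self):
        df = pd.DataFrame(
            {
                "subject": ["a"],
                "group": ["sham"],
                **{b: [np.nan] for b in DEFAULT_BANDS},
                "alpha_theta_ratio": [1.0],
            }
        )
        with pytest.raises(ValueError):
            FeatureTable(data=df, scenario="none")


def test_decibel_scenario_stabilizes_within_subject_variance():
    """Broadband gain jitter scales each subject's raw feature *spread*
    multiplicatively (a 2x-gain subject has 4x the within-subject power
    variance), so raw within-subject variances disperse widely across
    subjects; in the decibel domain the gain becomes an additive offset
    and the within-subject variances become comparable. This is the
    variance-stabilization that lets statistics fitted on training
    subjects transfer to unseen ones."""
    from wakeqeeg import CohortSpec, simulate_cohort
    from wakeqeeg.epoching import extract_wake_epochs
    from wakeqeeg.features import band_power_table

    spec = CohortSpec(
        duration_h=1.0, seed=9, subject_gain_sd_db=3.0, effect_db={},
    )
    epochsets = [extract_wake_epochs(r, h, 1) for r, h in simulate_cohort(spec)]
    table = band_power_table(epochsets)

    def within_var_dispersion(frame, band):
        within = frame.groupby("subject")[band].var(ddof=0)
        return np.var(np.log10(within))

    ft_none, _ = features_from_table(table, None, "none")
    ft_db, _ = features_from_table(table, None, "decibel_plus_feature")
    for band in DEFAULT_BANDS:
        disp_none = within_var_dispersion(ft_none.data, band)
        disp_db = within_var_dispersion(ft_db.data, band)
        assert disp_db < disp_none, band
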