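"""Shared fixtures: small synthetic cohorts reused across test modules.

The expensive fixtures (simulated cohorts and their band-power tables)
are session-scoped so the signal synthesis and filtering cost is paid
once.
"""

from __future__ import annotations

import numpy as np
import pytest

from wakeqeeg import CohortSpec, simulate_cohort
from wakeqeeg.epoching import extract_wake_epochs
from wakeqeeg.features import band_power_table


@pytest.fixture(scope="session")
def recovery_cohort():
    """5 sham + 4 TBI, 2-h recordings, strong effects (alpha -6 / theta +6 dB),
    no subject-level gain jitter — the parameter-recovery study condition."""
    spec = CohortSpec(
        duration_h=2.0,
        seed=0,
        subject_gain_sd_db=0.0,
        effect_db={"alpha": -6.0, "theta": 6.0},
    )
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def chance_cohort():
    """Zero-effect, zero-jitter cohort (4 h): no group signal by construction."""
    spec = CohortSpec(
        duration_h=4.0, seed=0, subject_gain_sd_db=0.0, effect_db={}
    )
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 2+2 cohort (1 h) for plumbing and bookkeeping tests."""
    spec = CohortSpec(n_sham=2, n_tbi=2, duration_h=1.0, seed=3)
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_power_table(small_cohort):
    _, cohort = small_cohort
    epochsets = [extract_wake_epochs(r, h, 1) for r, h in cohort]
    return epochsets, band_power_table(epochsets)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
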