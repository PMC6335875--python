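import numpy as np
import pandas as pd
import pytest

from sleepdebt.cohort import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject, 300-feature cohort with all feature classes present."""
    cfg = SyntheticConfig(
        n_subjects=12,
        n_features=300,
        n_trend=30,
        n_circadian=30,
        n_condition=30,
        n_mixed=10,
        trend_slope=0.05,
        circadian_amplitude=0.5,
        condition_effect=0.6,
        trait_sd=1.0,
        noise_sd=0.3,
        flag_rate=0.02,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, trait-free cohort for exact-arithmetic checks."""
    cfg = SyntheticConfig(
        n_subjects=4,
        n_features=40,
        n_trend=10,
        n_circadian=10,
        n_condition=10,
        n_mixed=0,
        trend_slope=0.05,
        circadian_amplitude=0.5,
        condition_effect=0.6,
        trait_sd=0.0,
        noise_sd=0.0,
        flag_rate=0.0,
        seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def regression_problem(rng):
    """Small dense linear problem with a known sparse signal."""
    n, p = 60, 12
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:3] = [2.0, -1.5, 1.0]
    y = X @ beta + 0.3 * rng.normal(size=n)
    return X, y, beta
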