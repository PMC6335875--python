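"""A-priori screening: power on planted effects, type-I calibration on null
features, and the two selection rules."""

import numpy as np
import pytest

from sleepdebt.cohort import SyntheticConfig, generate_cohort
from sleepdebt.screen import (
    circadian_test,
    condition_test,
    screen_features,
    select_a_priori,
    trend_test,
)


@pytest.fixture(scope="module")
def screen_cohort():
    """12 subjects, strong planted effects, plus 1000 null features for
    calibration."""
    cfg = SyntheticConfig(
        n_subjects=12, n_features=1150, n_trend=50, n_circadian=50,
        n_condition=50, n_mixed=0, trend_slope=0.05, circadian_amplitude=0.5,
        condition_effect=0.6, trait_sd=1.0, noise_sd=0.3, flag_rate=0.0, seed=21,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="module")
def screened(screen_cohort):
    matrix, meta, truth = screen_cohort
    return screen_features(matrix, meta, alpha_screen=0.05), truth, meta


def test_trend_power_and_sign_concordance(screened):
    screen, truth, _ = screened
    trend_ids = truth.index[truth["class"] == "trend"]
    sub = screen.loc[trend_ids]
    power = ((sub["p_sufficient"] < 0.05) & (sub["p_insufficient"] < 0.05)).mean()
    assert power > 0.9
    concordant = np.sign(sub["slope_sufficient"]) == np.sign(sub["slope_insufficient"])
    assert concordant.mean() > 0.9


def test_null_calibration_all_tests(screened):
    """Null-feature rejection rates stay near the 5% screening level."""
    screen, truth, _ = screened
    null_ids = truth.index[truth["class"] == "null"]
    sub = screen.loc[null_ids]
    for col in ("p_sufficient", "p_insufficient", "p_circ", "p_cond"):
        rate = (sub[col] < 0.05).mean()
        assert 0.01 < rate < 0.10, f"{col} rejection rate {rate}"


def test_noiseless_trend_feature_exact(clean_cohort):
    matrix, meta, truth = clean_cohort
    fid = truth.index[truth["class"] == "trend"][0]
    res = trend_test(matrix.values.loc[[fid]], meta)
    assert res["p_sufficient"].iloc[0] < 1e-12
    assert np.isclose(res["slope_sufficient"].iloc[0], truth.loc[fid, "a_g"], atol=1e-10)
    assert np.isclose(res["slope_insufficient"].iloc[0], truth.loc[fid, "a_g"], atol=1e-10)


def test_noiseless_pure_cosine_amplitude_exact(clean_cohort):
    matrix, meta, truth = clean_cohort
    fid = truth.index[truth["class"] == "circadian"][0]
    res = circadian_test(matrix.values.loc[[fid]], meta)
    assert np.isclose(res["amplitude"].iloc[0], truth.loc[fid, "b_g"], atol=1e-8)
    assert res["p_circ"].iloc[0] < 1e-12


def test_circadian_amplitude_recovered_within_20pct(screened):
    screen, truth, _ = screened
    circ_ids = truth.index[truth["class"] == "circadian"]
    sub = screen.loc[circ_ids]
    assert (sub["p_circ"] < 0.05).mean() > 0.9
    rel_err = np.abs(sub["amplitude"] - truth.loc[circ_ids, "b_g"]) / truth.loc[circ_ids, "b_g"]
    assert rel_err.median() < 0.2


def test_condition_pairing_removes_trait_variance(screened):
    """Paired test on subject means is well powered despite trait_sd >> effect."""
    screen, truth, _ = screened
    cond_ids = truth.index[truth["class"] == "condition"]
    sub = screen.loc[cond_ids]
    assert (sub["p_cond"] < 0.05).mean() > 0.9
    signed_err = sub["shift"] * np.sign(truth.loc[cond_ids, "delta_g"])
    assert (signed_err > 0).mean() > 0.95


def test_condition_shift_zero_without_effect(clean_cohort):
    matrix, meta, truth = clean_cohort
    fid = truth.index[truth["class"] == "trend"][0]  # no condition effect
    res = condition_test(matrix.values.loc[[fid]], meta)
    assert abs(res["shift"].iloc[0]) < 1e-10


class TestSelection:
    def test_recovery_and_specificity(self, screened):
        screen, truth, _ = screened
        hours = set(select_a_priori(screen, "hours_awake"))
        suff = set(select_a_priori(screen, "sleep_sufficiency"))
        trend_ids = set(truth.index[truth["class"] == "trend"])
        cond_ids = set(truth.index[truth["class"] == "condition"])
        assert len(hours & trend_ids) / len(trend_ids) >= 0.8
        assert len(suff & cond_ids) / len(cond_ids) >= 0.8
        # cross-contamination stays within false-positive expectation
        assert len(hours & cond_ids) <= max(3, 0.06 * len(cond_ids))
        assert len(suff & trend_ids) <= max(3, 0.06 * len(trend_ids))

    def test_sets_disjoint(self, screened):
        screen, _, _ = screened
        hours = set(select_a_priori(screen, "hours_awake"))
        suff = set(select_a_priori(screen, "sleep_sufficiency"))
        assert hours.isdisjoint(suff)

    def test_mixed_features_excluded_from_both(self):
        cfg = SyntheticConfig(
            n_subjects=12, n_features=120, n_trend=0, n_circadian=0,
            n_condition=0, n_mixed=20, trend_slope=0.05, condition_effect=0.6,
            trait_sd=1.0, noise_sd=0.3, flag_rate=0.0, seed=13,
        )
        matrix, meta, truth = generate_cohort(cfg)
        screen = screen_features(matrix, meta)
        mixed = set(truth.index[truth["class"] == "mixed"])
        hours = set(select_a_priori(screen, "hours_awake"))
        suff = set(select_a_priori(screen, "sleep_sufficiency"))
        assert not (mixed & hours)
        # a mixed feature with a detected trend cannot enter sleep_sufficiency
        assert len(mixed & suff) <= 2

    def test_positive_criteria_monotone_in_alpha(self, screened):
        """The qualifying pools (trend-in-both / condition-difference) shrink
        as the screening level tightens; the full sets need not, because the
        negated exclusion criteria relax simultaneously."""
        screen, _, _ = screened
        for a_tight, a_loose in ((0.001, 0.05), (0.01, 0.05)):
            trend_tight = (screen["p_sufficient"] < a_tight) & (screen["p_insufficient"] < a_tight)
            trend_loose = (screen["p_sufficient"] < a_loose) & (screen["p_insufficient"] < a_loose)
            assert (trend_tight & ~trend_loose).sum() == 0
            cond_tight = screen["p_cond"] < a_tight
            cond_loose = screen["p_cond"] < a_loose
            assert (cond_tight & ~cond_loose).sum() == 0

    def test_all_null_cohort_small_sets(self):
        cfg = SyntheticConfig(
            n_subjects=12, n_features=400, n_trend=0, n_circadian=0,
            n_condition=0, n_mixed=0, trait_sd=1.0, noise_sd=0.3,
            flag_rate=0.0, seed=17,
        )
        matrix, meta, _ = generate_cohort(cfg)
        screen = screen_features(matrix, meta)
        hours = select_a_priori(screen, "hours_awake")
        suff = select_a_priori(screen, "sleep_sufficiency")
        # expected size ~ n_features * false-positive mass, small
        assert len(hours) < 0.03 * 400
        assert len(suff) < 0.10 * 400
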