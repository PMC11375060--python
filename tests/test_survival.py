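"""Survival engine: Kaplan–Meier against hand computation and lifelines,
Cox fits against a brute-force Efron partial-likelihood maximizer, window
restriction rules, and 2x2 association statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import glycoscreen as gs
from glycoscreen.survival import SingularDesignError, _null_partial_loglik

from conftest import efron_partial_loglik, grid_maximize_beta


# ---------------------------------------------------------------- Kaplan–Meier

def test_km_hand_computed_product_limit():
    est = gs.km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
    assert list(est.times) == [1.0, 3.0]
    assert est.survival[0] == pytest.approx(2 / 3)
    assert est.survival[1] == pytest.approx(0.0)
    assert list(est.at_risk) == [3, 1]


def test_km_all_censored_stays_at_one():
    est = gs.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
    assert est.times.size == 0  # no event times: S identically 1


def test_km_invariant_to_duplicating_subjects():
    t, e = [1.0, 2.0, 4.0, 7.0], [1, 0, 1, 1]
    a = gs.km_estimate(t, e)
    b = gs.km_estimate(t * 2, e * 2)
    np.testing.assert_allclose(a.survival, b.survival)
    np.testing.assert_array_equal(a.times, b.times)


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    t = rng.exponential(2.0, 40)
    est = gs.km_estimate(t, np.ones(40, int))
    for time, s in zip(est.times, est.survival):
        assert s == pytest.approx((t > time).mean())


def test_km_matches_lifelines():
    """Independent cross-check of the product-limit computation."""
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(1)
    t = rng.exponential(3.0, 60)
    e = rng.integers(0, 2, 60)
    est = gs.km_estimate(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    ours = pd.Series(est.survival, index=est.times)
    theirs = kmf.survival_function_["KM_estimate"]
    for time, s in ours.items():
        assert s == pytest.approx(theirs.loc[time], abs=1e-12)


# ------------------------------------------------------------------- Cox fits

FIXTURES = [
    # (marker, times, events) — all with <= 8 subjects
    ([1, 0, 1, 0, 1, 0], [1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1]),
    ([0.5, -1.2, 0.3, 2.0, -0.7, 0.0, 1.1, -0.4],
     [2, 2, 3, 5, 5, 5, 7, 9], [1, 1, 0, 1, 1, 0, 1, 1]),  # ties for Efron
    ([1.0, 2.0, 0.5, 1.5, -0.5, 0.0], [4, 1, 6, 3, 8, 2], [1, 0, 1, 1, 0, 1]),
]


@pytest.mark.parametrize("marker,times,events", FIXTURES)
def test_cox_matches_bruteforce_efron_grid(marker, times, events):
    fit = gs.cox_fit(np.array(marker, float), times, events)
    beta_hat = np.log(fit.hr)
    beta_grid = grid_maximize_beta(marker, times, events)
    assert abs(beta_hat - beta_grid) < 1e-4
    assert fit.ci_low <= fit.hr <= fit.ci_high


def test_cox_degenerate_designs_raise():
    t, e = [1.0, 2, 3, 4], [1, 1, 1, 0]
    with pytest.raises(SingularDesignError):
        gs.cox_fit(np.ones(4), t, e)  # constant marker
    X = pd.DataFrame({"m": [0.1, 0.9, 0.3, 0.7], "m2": [0.1, 0.9, 0.3, 0.7]})
    with pytest.raises(SingularDesignError):
        gs.cox_fit(X, t, e, marker="m")  # duplicated covariate
    with pytest.raises(ValueError):
        gs.cox_fit([0.1, 0.9, 0.3, 0.7], t, [0, 0, 0, 0])  # no events


def test_cox_breslow_not_available():
    with pytest.raises(NotImplementedError):
        gs.cox_fit([0.0, 1.0], [1.0, 2.0], [1, 1], ties="breslow")


def test_cox_likelihood_ratio_close_to_wald_at_moderate_n():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(150)
    t = rng.exponential(1.0 / (0.1 * np.exp(0.4 * x)))
    e = np.ones(150, int)
    wald = gs.cox_fit(x, t, e, pvalue="wald")
    lr = gs.cox_fit(x, t, e, pvalue="likelihood-ratio")
    assert wald.hr == pytest.approx(lr.hr)
    assert np.log10(wald.p) == pytest.approx(np.log10(lr.p), abs=0.5)


def test_null_partial_loglik_matches_oracle_at_zero():
    t = np.array([2.0, 2, 3, 5, 5, 5, 7, 9])
    e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    x = np.zeros(8)
    assert _null_partial_loglik(t, e) == pytest.approx(
        efron_partial_loglik(0.0, x, t, e)
    )


# ------------------------------------------------------- dichotomize / window

def test_dichotomize_by_mean_rules():
    labels = gs.dichotomize_by_mean(np.array([1.0, 3.0]))
    assert list(labels) == ["LOW", "HIGH"]
    # value exactly at the mean is HIGH
    assert list(gs.dichotomize_by_mean(np.array([2.0, 2.0]))) == ["HIGH", "HIGH"]
    shifted = gs.dichotomize_by_mean(np.array([1.0, 3.0]) + 100.0)
    assert list(shifted) == ["LOW", "HIGH"]


def test_dichotomize_reference_subset():
    vals = np.array([0.0, 10.0, 4.0, 6.0])
    ref = np.array([False, False, True, True])  # mean 5
    assert list(gs.dichotomize_by_mean(vals, ref)) == ["LOW", "HIGH", "LOW", "HIGH"]


def test_restrict_window_rules():
    t, e = gs.restrict_window([7.0], [1], "early")
    assert t[0] == 5.0 and e[0] == 0
    t, e = gs.restrict_window([3.0], [1], "late")
    assert t.size == 0  # excluded
    t, e = gs.restrict_window([6.0, 6.0], [1, 1], "early")
    assert e.sum() == 0
    t, e = gs.restrict_window([6.0, 6.0], [1, 1], "late")
    assert e.sum() == 2 and np.allclose(t, 1.0)
    # events beyond 20 y are censored at the 15 y cap in the late window
    t, e = gs.restrict_window([22.0], [1], "late")
    assert t[0] == 15.0 and e[0] == 0


def test_restrict_window_early_idempotent():
    times = np.array([1.0, 4.9, 5.0, 8.0, 20.0])
    events = np.array([1, 1, 1, 0, 1])
    t1, e1 = gs.restrict_window(times, events, "early")
    t2, e2 = gs.restrict_window(t1, e1, "early")
    np.testing.assert_array_equal(t1, t2)
    np.testing.assert_array_equal(e1, e2)


# ------------------------------------------------------------------ screening

def test_prognostic_screen_flags_planted_gene():
    cfg = gs.SimConfig(seed=21, n_samples=2000, n_genes=4,
                       planted_log_hr={"G0001": float(np.log(1.5))})
    co = gs.simulate_cohort(cfg)
    res = gs.prognostic_screen(co)
    assert bool(res.loc["G0001", "significant_uni"])
    assert res.loc["G0001", "direction"] == "bad"
    assert res.loc["G0001", "hr_uni"] == pytest.approx(1.5, rel=0.15)
    # planted effect survives covariate adjustment
    assert bool(res.loc["G0001", "significant_multi"])


def test_prognostic_screen_mean_split_mode(small_cohort):
    res = gs.prognostic_screen(small_cohort, marker_mode="mean-split",
                               multivariable=False)
    assert res["converged"].all()
    assert (res["hr_uni"] > 0).all()


# ----------------------------------------------------------------- odds ratio

def test_odds_ratio_cross_product():
    or_, lo, hi, p = gs.odds_ratio_2x2(30, 70, 10, 90)
    assert or_ == pytest.approx(27 / 7)
    assert lo < or_ < hi


def test_odds_ratio_equal_proportions():
    or_, lo, hi, p = gs.odds_ratio_2x2(10, 10, 10, 10)
    assert or_ == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


def test_odds_ratio_zero_cell_haldane():
    or_, lo, hi, p = gs.odds_ratio_2x2(0, 20, 10, 10)
    assert np.isfinite([or_, lo, hi]).all()
    with pytest.raises(ValueError):
        gs.odds_ratio_2x2(0, 0, 0, 0)


@given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30))
def test_odds_ratio_transpose_symmetry(a, b, c, d):
    """Swapping rows inverts the OR; the chi-square p is unchanged."""
    or1, *_, p1 = gs.odds_ratio_2x2(a, b, c, d)
    or2, *_, p2 = gs.odds_ratio_2x2(c, d, a, b)
    assert or1 == pytest.approx(1.0 / or2)
    assert p1 == pytest.approx(p2)
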