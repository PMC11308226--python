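"""Discrimination and calibration metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iecv.glm import DegenerateOutcomeError, SeparationError, fit_logistic
from iecv.metrics import (calibration_curve, calibration_intercept,
                          calibration_slope, harrell_c, model_based_c)


def brute_force_c(p, y):
    """O(n^2) pair enumeration: concordant 1, tied 1/2."""
    p, y = np.asarray(p, float), np.asarray(y, float)
    num = den = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            den += 1
            if p[i] > p[j]:
                num += 1
            elif p[i] == p[j]:
                num += 0.5
    return num / den


# -- Harrell's c ----------------------------------------------------------

@pytest.mark.parametrize("p,y,expected", [
    ([0.9, 0.1], [1, 0], 1.0),
    ([0.2, 0.4, 0.4, 0.8], [0, 1, 0, 1], 0.875),
    ([0.0, 1.0, 0.0, 1.0], [0, 1, 0, 1], 1.0),   # p = y identity
    ([0.3, 0.3, 0.3, 0.3], [0, 1, 0, 1], 0.5),   # all tied
])
def test_harrell_c_known_values(p, y, expected):
    assert harrell_c(p, y).value == pytest.approx(expected, abs=1e-12)


def test_harrell_c_equals_brute_force_on_random_instances():
    """Midrank implementation == exhaustive pair count, exactly, 200x."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = rng.integers(4, 51)
        # discretized probabilities force plenty of ties
        p = rng.integers(0, 6, n) / 5.0
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert harrell_c(p, y).value == pytest.approx(
            brute_force_c(p, y), abs=1e-12)


def test_harrell_c_degenerate_outcome_raises():
    with pytest.raises(DegenerateOutcomeError):
        harrell_c([0.2, 0.8], [1, 1])


@given(st.integers(0, 2 ** 32 - 1))
@settings(max_examples=25, deadline=None)
def test_harrell_c_complement_and_monotone_invariance(seed):
    """c(1-p, y) = 1 - c(p, y); c invariant to strictly monotone maps."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    p = rng.integers(0, 8, n) / 8.0
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    c = harrell_c(p, y).value
    assert harrell_c(1.0 - p, y).value == pytest.approx(1.0 - c, abs=1e-12)
    assert harrell_c(np.exp(3.0 * p), y).value == pytest.approx(c, abs=1e-12)


def test_harrell_c_ci_orders_and_bounds():
    rng = np.random.default_rng(8)
    p = rng.random(200)
    y = (rng.random(200) < p).astype(int)
    est = harrell_c(p, y)
    assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0
    boot = harrell_c(p, y, ci_method="bootstrap", n_boot=200, seed=1)
    assert boot.se == pytest.approx(est.se, rel=0.5)


# -- model-based c --------------------------------------------------------

@pytest.mark.parametrize("p,expected", [
    ([0.5, 0.5], 0.5),
    ([0.2, 0.8], 0.64 / 0.68),
    ([0.0, 1.0], 1.0),
])
def test_model_based_c_known_values(p, expected):
    assert model_based_c(p).value == pytest.approx(expected, abs=1e-12)


def test_model_based_c_is_expected_harrell_c():
    """Equals the Monte-Carlo mean of c(p, Y), Y ~ Bernoulli(p)."""
    rng = np.random.default_rng(77)
    p = rng.beta(2, 2, size=100)
    exact = model_based_c(p).value
    draws = []
    for _ in range(10_000):
        y = (rng.random(100) < p).astype(float)
        if y.min() == y.max():
            continue
        draws.append(harrell_c(p, y).value)
    mc = np.mean(draws)
    mc_se = np.std(draws, ddof=1) / np.sqrt(len(draws))
    assert abs(mc - exact) < 3.0 * mc_se


def test_model_based_c_random_pair_approximation_close_to_exact():
    rng = np.random.default_rng(5)
    p = rng.beta(2, 3, size=3000)  # beyond the exact-evaluation limit
    approx = model_based_c(p, seed=1)
    assert "approximate" in approx.note
    # exact oracle evaluated directly on the full pair set
    pm = np.minimum.outer(p, p)
    pM = np.maximum.outer(p, p)
    iu = np.triu_indices(p.size, k=1)
    exact = (pM * (1 - pm))[iu].sum() / (
        (np.outer(p, 1 - p) + np.outer(1 - p, p))[iu].sum())
    assert approx.value == pytest.approx(exact, abs=2e-3)


def test_model_based_c_error_cases():
    with pytest.raises(ValueError):
        model_based_c([0.5])
    with pytest.raises(ZeroDivisionError):
        model_based_c([1.0, 1.0])


# -- calibration intercept / slope ---------------------------------------

def test_calibration_intercept_zero_by_symmetric_construction():
    """13/50 events at lp=-1 and 37/50 at lp=+1 solve the score
    equation at exactly a=0 (expit(-1) + expit(1) = 1)."""
    lp = np.r_[np.full(50, -1.0), np.full(50, 1.0)]
    y = np.r_[np.ones(13), np.zeros(37), np.ones(37), np.zeros(13)]
    est = calibration_intercept(lp, y)
    # oracle: Newton solve of sum(y - expit(a + lp)) = 0
    a = 0.0
    for _ in range(50):
        pa = 1 / (1 + np.exp(-(a + lp)))
        a -= (pa.sum() - y.sum()) / (pa * (1 - pa)).sum()
    assert a == pytest.approx(0.0, abs=1e-10)
    assert est.value == pytest.approx(a, abs=1e-6)


def test_calibration_intercept_shift_identity():
    """Adding delta to a calibrated lp moves the intercept to -delta."""
    lp = np.r_[np.full(50, -1.0), np.full(50, 1.0)]
    y = np.r_[np.ones(13), np.zeros(37), np.ones(37), np.zeros(13)]
    est = calibration_intercept(lp + 0.7, y)
    assert est.value == pytest.approx(-0.7, abs=1e-6)


def test_refit_predictions_have_intercept_zero_slope_one():
    """Predictions from a model ML-refit on the evaluation data are
    perfectly calibrated (score equations)."""
    rng = np.random.default_rng(12)
    X = rng.normal(size=(500, 2))
    y = (rng.random(500) < 1 / (1 + np.exp(-(0.8 * X[:, 0])))).astype(float)
    fit = fit_logistic(X, y)
    lp = fit.linear_predictor(X)
    assert calibration_intercept(lp, y).value == pytest.approx(0, abs=1e-5)
    assert calibration_slope(lp, y).value == pytest.approx(1, abs=1e-5)


def test_calibration_slope_recovery_large_sample():
    rng = np.random.default_rng(100)
    lp = rng.normal(0.5, 1.2, 100_000)
    y = (rng.random(lp.size) < 1 / (1 + np.exp(-lp))).astype(float)
    assert calibration_slope(lp, y).value == pytest.approx(1.0, abs=0.05)
    assert calibration_intercept(lp, y).value == pytest.approx(0.0, abs=0.05)


def test_calibration_slope_zero_when_outcome_independent():
    est = calibration_slope(np.array([-1.0, 1.0, -1.0, 1.0]),
                            np.array([0.0, 1.0, 1.0, 0.0]))
    assert est.value == pytest.approx(0.0, abs=1e-8)


def test_calibration_slope_error_contracts():
    with pytest.raises(ValueError, match="constant"):
        calibration_slope(np.ones(4), np.array([0.0, 1.0, 0.0, 1.0]))
    with pytest.raises(SeparationError):
        calibration_slope(np.array([-2.0, -1.0, 1.0, 2.0]),
                          np.array([0.0, 0.0, 1.0, 1.0]))


# -- calibration curves ---------------------------------------------------

def test_calibration_curve_calibrated_bins_near_diagonal():
    rng = np.random.default_rng(42)
    p = rng.uniform(0.05, 0.95, 20_000)
    y = (rng.random(p.size) < p).astype(float)
    curve = calibration_curve(p, y)
    se = np.sqrt(curve.bin_pred_mean * (1 - curve.bin_pred_mean)
                 / curve.bin_counts)
    assert np.all(np.abs(curve.bin_obs_frac - curve.bin_pred_mean) < 3 * se)
    assert curve.bin_counts.sum() == p.size


def test_calibration_curve_constant_predictions_single_bin():
    p = np.full(100, 0.3)
    y = np.r_[np.ones(30), np.zeros(70)]
    curve = calibration_curve(p, y)
    assert curve.bin_pred_mean.size == 1
    assert curve.bin_pred_mean[0] == pytest.approx(0.3)
    assert curve.bin_obs_frac[0] == pytest.approx(0.3)


def test_calibration_curve_detects_overconfidence():
    """With E[y|p] = p^2, observed fractions sit below the diagonal."""
    rng = np.random.default_rng(9)
    p = rng.uniform(0.1, 0.9, 30_000)
    y = (rng.random(p.size) < p ** 2).astype(float)
    curve = calibration_curve(p, y)
    # oracle: per-bin E[y] = E[p^2 | bin]; compare against bin means
    mid = curve.bin_pred_mean < 0.9
    assert np.all(curve.bin_obs_frac[mid] < curve.bin_pred_mean[mid])


def test_calibration_curve_bad_bins():
    with pytest.raises(ValueError):
        calibration_curve([0.1, 0.2, 0.3], [0, 1, 0], n_bins=1)
    with pytest.raises(ValueError):
        calibration_curve([0.1, 0.2], [0, 1], n_bins=5)
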