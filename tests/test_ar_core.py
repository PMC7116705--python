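"""Autocovariance, Levinson-Durbin and conditional likelihood primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import solve_toeplitz

from cpscan import (DegenerateSeriesError, ar_conditional_loglik,
                    autocovariance, fixed_order, levinson_durbin,
                    pooled_autocovariance, simulate_segment, SegmentSpec)


class TestAutocovariance:
    def test_alternating_series(self):
        g = autocovariance([1, -1, 1, -1], 1)
        assert g[0] == pytest.approx(1.0)
        assert g[1] == pytest.approx(-0.75)

    def test_lag0_is_mean_of_squares(self, rng):
        x = rng.standard_normal(50)
        assert autocovariance(x, 0)[0] == pytest.approx(np.mean(x ** 2))

    def test_constant_series_mean_corrected_is_zero(self):
        g = autocovariance(np.full(20, 3.7), 3, mean_correct=True)
        assert np.allclose(g, 0.0)

    def test_explicit_mean_value(self, rng):
        x = rng.standard_normal(40) + 5.0
        g1 = autocovariance(x, 2, mean_correct=True, mean_value=5.0)
        g2 = autocovariance(x - 5.0, 2)
        assert np.allclose(g1, g2)

    def test_lag_too_large_rejected(self):
        with pytest.raises(ValueError):
            autocovariance([1.0, 2.0, 3.0], 3)


class TestPooledAutocovariance:
    def test_identical_segments_reduce_to_single(self, rng):
        x = rng.standard_normal(60)
        c = pooled_autocovariance(x, x, 4)
        assert np.allclose(c.values, autocovariance(x, 4))

    def test_direct_sum(self):
        c = pooled_autocovariance([1, -1, 1, -1], [2, -2, 2, -2], 1)
        assert c.values[0] == pytest.approx(2.5)
        assert (c.n1, c.n2) == (4, 4)

    def test_constant_segments_mean_corrected(self):
        c = pooled_autocovariance(np.full(10, 2.0), np.full(15, 2.0), 2,
                                  mean_correct=True)
        assert np.allclose(c.values, 0.0)

    def test_pooled_mean_centering(self, rng):
        # both segments centred by the single pooled mean, not their own
        x = rng.standard_normal(30) + 1.0
        y = rng.standard_normal(50) - 1.0
        mu = (x.sum() + y.sum()) / 80
        expect = (np.dot(x - mu, x - mu) + np.dot(y - mu, y - mu)) / 80
        c = pooled_autocovariance(x, y, 0, mean_correct=True)
        assert c.values[0] == pytest.approx(expect)


class TestLevinsonDurbin:
    def test_white_noise(self):
        fit = levinson_durbin([1.0, 0.0], 1)
        assert fit.coeffs == pytest.approx([0.0])
        assert fit.innovation_var == pytest.approx(1.0)

    def test_scalar_yule_walker(self):
        fit = levinson_durbin([1.0, -0.75], 1)
        assert fit.coeffs == pytest.approx([0.75])
        assert fit.innovation_var == pytest.approx(0.4375)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(1, 10))
    def test_matches_direct_toeplitz_solve(self, seed, p):
        # sample autocovariances of a random series are positive definite
        x = np.random.default_rng(seed).standard_normal(80)
        g = autocovariance(x, p)
        fit = levinson_durbin(g, p)
        direct = -solve_toeplitz(g[:p], g[1:p + 1]) if p else np.empty(0)
        assert np.allclose(fit.coeffs, direct, rtol=1e-10, atol=1e-12)
        assert fit.innovation_var == pytest.approx(
            g[0] + np.dot(g[1:p + 1], fit.coeffs), rel=1e-10)

    def test_variance_non_increasing_in_order(self, rng):
        g = autocovariance(rng.standard_normal(200), 8)
        variances = [levinson_durbin(g, p).innovation_var for p in range(9)]
        assert np.all(np.diff(variances) <= 1e-12)

    def test_degenerate_input_raises(self):
        with pytest.raises(DegenerateSeriesError):
            levinson_durbin([0.0, 0.0], 1)
        with pytest.raises(DegenerateSeriesError):
            levinson_durbin([1.0, 1.0, 1.0], 2)  # perfectly correlated


class TestConditionalLoglik:
    def test_standard_normal_at_zero(self):
        fit = levinson_durbin([1.0], 0)
        ll = ar_conditional_loglik([0.0, 0.0, 0.0], fit, 0, 2)
        assert ll == pytest.approx(-1.5 * math.log(2 * math.pi))

    def test_additive_over_partition(self, rng):
        x = rng.standard_normal(100)
        fit = levinson_durbin(autocovariance(x, 2), 2)
        whole = ar_conditional_loglik(x, fit, 2, 99)
        split = (ar_conditional_loglik(x, fit, 2, 49)
                 + ar_conditional_loglik(x, fit, 50, 99))
        assert whole == pytest.approx(split)

    def test_variance_scale_identity(self, rng):
        from cpscan import ARFit
        x = rng.standard_normal(60)
        fit = levinson_durbin(autocovariance(x, 1), 1)
        double = ARFit(order=1, coeffs=fit.coeffs,
                       innovation_var=2 * fit.innovation_var)
        base = ar_conditional_loglik(x, fit, 1, 59)
        idx = np.arange(1, 60)
        rss = np.sum((x[idx] + fit.coeffs[0] * x[idx - 1]) ** 2)
        expect = (base - 0.5 * 59 * math.log(2.0)
                  + rss / (2 * fit.innovation_var)
                  - rss / (4 * fit.innovation_var))
        assert ar_conditional_loglik(x, double, 1, 59) == pytest.approx(expect)

    def test_near_maximal_at_yule_walker_fit(self):
        x = simulate_segment(SegmentSpec(ar_coeffs=(0.6,), length=10_000), 5).values
        fit = levinson_durbin(autocovariance(x, 1), 1)
        from cpscan import ARFit
        base = ar_conditional_loglik(x, fit)
        for delta in (-0.05, 0.05):
            pert = ARFit(order=1, coeffs=fit.coeffs + delta,
                         innovation_var=fit.innovation_var)
            assert ar_conditional_loglik(x, pert) < base

    def test_window_too_short(self):
        fit = levinson_durbin([1.0, -0.5, 0.3], 2)
        with pytest.raises(ValueError):
            ar_conditional_loglik([1.0, 2.0, 3.0], fit, start=1, end=2)


class TestFixedOrder:
    @pytest.mark.parametrize("t_min,expected", [
        (128, 4),   # log10(128)^2 = 4.44
        (100, 4),   # exact power of the base
        (54, 3),    # log10(54)^2 = 3.0012, just over the integer boundary
        (172, 4),   # last length giving order 4
        (173, 5),
    ])
    def test_default_rule(self, t_min, expected):
        assert fixed_order(t_min) == expected

    def test_configurable_base_and_exponent(self):
        assert fixed_order(1024, upsilon=2.0, log_base=math.e) == 48
        assert fixed_order(100, upsilon=1.5, log_base=10.0) == 2

    def test_parameter_recovery_ar1(self):
        # estimation convention: generative phi = 0.7 appears as beta = -0.7
        x = simulate_segment(SegmentSpec(ar_coeffs=(0.7,), length=100_000), 11)
        fit = levinson_durbin(autocovariance(x, 1), 1)
        assert fit.coeffs[0] == pytest.approx(-0.7, abs=0.02)
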