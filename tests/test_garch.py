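import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vretvol.garch import (
    conditional_variance_path,
    fit_ar,
    fit_ar_garch,
    fit_garch,
    one_step_forecasts,
    select_ar_order,
    volatility_summary,
)
from vretvol.synthetic import generate_garch_innovations


def simulate_ar1(alpha, n, sigma, seed):
    rng = np.random.default_rng(seed)
    z = np.zeros(n)
    eps = rng.normal(0, sigma, n)
    for t in range(1, n):
        z[t] = alpha * z[t - 1] + eps[t]
    return z


class TestFitAR:
    def test_recovers_ar1_coefficient(self):
        z = simulate_ar1(0.7, 5000, 0.1, seed=42)
        fit = fit_ar(z, 1)
        assert fit.coeffs[0] == pytest.approx(0.7, abs=0.02)
        assert fit.residuals.size == z.size - 1

    def test_p0_reduces_to_sample_mean(self):
        z = np.array([1.0, 2.0, 3.0, 4.0, 7.0])
        fit = fit_ar(z, 0)
        assert fit.intercept == pytest.approx(z.mean())
        np.testing.assert_allclose(fit.residuals, z - z.mean())

    def test_noiseless_recursion_exact(self):
        z = np.array([1.0 * 0.5**k for k in range(80)])
        fit = fit_ar(z, 1)
        assert fit.coeffs[0] == pytest.approx(0.5, abs=1e-10)

    def test_rejects_too_short_and_constant(self):
        with pytest.raises(ValueError, match="too short"):
            fit_ar(np.arange(4.0), 2)
        with pytest.raises(ValueError, match="singular"):
            fit_ar(np.ones(100), 1)


class TestSelectOrder:
    def test_white_noise_selects_zero(self):
        # BIC penalises spurious lags: majority of replicates pick p=0
        picks = [
            select_ar_order(np.random.default_rng(s).standard_normal(1000), 5, "bic")
            for s in range(10)
        ]
        assert sum(p == 0 for p in picks) >= 8

    def test_strong_ar1_selects_one(self):
        picks = [select_ar_order(simulate_ar1(0.8, 1000, 1.0, s), 5, "bic") for s in range(10)]
        assert sum(p == 1 for p in picks) >= 8

    def test_short_series_reduces_p_max_with_warning(self):
        z = np.random.default_rng(0).standard_normal(14)
        with pytest.warns(UserWarning, match="reduced"):
            p = select_ar_order(z, 10, "bic")
        assert 0 <= p <= 4


class TestConditionalVariancePath:
    def test_constant_at_delta_when_no_feedback(self):
        path = conditional_variance_path(0.7, 0.0, 0.0, np.random.standard_normal(50), init=0.7)
        np.testing.assert_allclose(path, 0.7)

    def test_direct_substitution(self):
        path = conditional_variance_path(0.5, 0.2, 0.3, [1.0, 0.0], init=1.0)
        assert path[0] == 1.0
        assert path[1] == pytest.approx(1.0)

    def test_spike_decays_geometrically(self):
        # after a single spike with zero subsequent residuals the excess
        # variance over the delta-only fixed point decays at rate gamma
        delta, beta, gamma = 0.1, 0.2, 0.6
        resid = np.array([5.0] + [0.0] * 20)
        path = conditional_variance_path(delta, beta, gamma, resid, init=1.0)
        fixed = delta / (1 - gamma)
        excess = path[2:] - fixed
        ratios = excess[1:] / excess[:-1]
        np.testing.assert_allclose(ratios, gamma, rtol=1e-8)

    def test_negative_delta_rejected_when_constrained(self):
        with pytest.raises(ValueError):
            conditional_variance_path(-0.1, 0.1, 0.1, [1.0, 2.0], constrained=True)


class TestFitGarch:
    def test_parameter_recovery_median_error(self):
        errs = []
        for r in range(20):
            tau = generate_garch_innovations(
                3000, 0.1, 0.1, 0.8, np.random.default_rng(100 + r)
            )
            d, b, g, ll, conv = fit_garch(tau)
            assert conv
            errs.append(abs(b + g - 0.9))
        assert np.median(errs) < 0.05

    def test_homoskedastic_limit_hits_boundary(self):
        tau = np.random.default_rng(1).standard_normal(2000) * 2.0
        d, b, g, ll, conv = fit_garch(tau)
        assert d == pytest.approx(np.var(tau), rel=1e-6)
        assert b == 0.0 and g == 0.0

    def test_deterministic_refit(self):
        tau = generate_garch_innovations(1000, 0.1, 0.1, 0.8, np.random.default_rng(5))
        assert fit_garch(tau) == fit_garch(tau)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_garch(np.zeros(100))

    def test_unconstrained_mode_warns_outside_region(self):
        # near-integrated data can push the raw QMLE outside stationarity
        tau = generate_garch_innovations(500, 0.05, 0.15, 0.84, np.random.default_rng(11))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d, b, g, ll, conv = fit_garch(tau, constrained=False)
        assert np.isfinite(ll)


class TestARGarch:
    def test_loglik_dominates_constant_variance_nested_model(self):
        for seed in range(5):
            tau = generate_garch_innovations(800, 0.1, 0.1, 0.8, np.random.default_rng(seed))
            z = 50 + tau
            fit = fit_ar_garch(z, p=1)
            assert fit.loglik >= fit.ar.loglik - 1e-6

    def test_variance_path_positive_and_std_resid_consistent(self):
        tau = generate_garch_innovations(600, 0.2, 0.1, 0.7, np.random.default_rng(3))
        fit = fit_ar_garch(100 + tau, p=1)
        assert np.all(fit.cond_var_path > 0)
        np.testing.assert_allclose(
            fit.std_resid, fit.ar.residuals / np.sqrt(fit.cond_var_path)
        )

    def test_short_or_flat_series_rejected(self):
        with pytest.raises(ValueError):
            fit_ar_garch(np.random.standard_normal(30))
        with pytest.raises(ValueError):
            fit_ar_garch(np.ones(100))


class TestVolatilitySummary:
    def test_printed_variance_equation_coefficients(self):
        # session-1 time-on-task variance equation: persistence = -0.21 + 1.12
        s = volatility_summary((1.06, -0.21, 1.12))
        assert s.persistence == pytest.approx(0.91)

    def test_half_life_closed_form(self):
        s = volatility_summary((0.1, 0.45, 0.46))
        assert s.half_life_steps == pytest.approx(math.log(0.5) / math.log(0.91))

    def test_unconditional_variance(self):
        s = volatility_summary((0.5, 0.2, 0.3))
        assert s.uncond_var == pytest.approx(1.0)
        assert s.half_life_steps == pytest.approx(1.0)

    def test_nonstationary_and_nonpositive_persistence(self):
        assert volatility_summary((0.1, 0.5, 0.6)).half_life_steps == math.inf
        assert math.isnan(volatility_summary((0.1, -0.2, 0.1)).half_life_steps)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0.01, 0.98),
        st.floats(0.001, 0.009),
    )
    def test_half_life_monotone_in_persistence(self, pers, bump):
        lo = volatility_summary((0.1, 0.0, pers)).half_life_steps
        hi = volatility_summary((0.1, 0.0, pers + bump)).half_life_steps
        assert hi > lo


def test_one_step_forecasts_align_with_residuals():
    z = simulate_ar1(0.6, 500, 1.0, seed=9)
    fit = fit_ar(z, 1)
    actual, fc = one_step_forecasts(fit, z)
    np.testing.assert_allclose(actual - fc, fit.residuals)
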