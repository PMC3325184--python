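import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from popcode.psychometrics import (
    WeibullBootstrapGenerator,
    binomial_ci,
    fit_weibull,
    fit_weibull_fixed_pse,
    learning_regression,
    matching_frequency,
    parametric_bootstrap,
    pse_monte_carlo_test,
    threshold,
    weibull,
)
from popcode.spectra import ParameterError


class TestWeibullFunction:
    def test_value_at_alpha(self):
        assert weibull(5.5, 5.5, 3.0, 0.5, 0.0) == pytest.approx(
            0.5 + 0.5 * (1 - np.exp(-1)), abs=1e-12)

    def test_limits(self):
        assert weibull(1e-9, 5.5, 3.0, 0.5, 0.02) == pytest.approx(0.5, abs=1e-12)
        assert weibull(1e6, 5.5, 3.0, 0.5, 0.02) == pytest.approx(0.98, abs=1e-12)

    @given(st.floats(0.1, 10.0), st.floats(0.5, 8.0), st.floats(0.0, 0.06))
    def test_monotone_and_bounded(self, alpha, beta, lam):
        x = np.geomspace(0.01 * alpha, 100 * alpha, 50)
        p = weibull(x, alpha, beta, 0.5, lam)
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0.5) & (p <= 1 - lam + 1e-12))

    def test_invalid_arguments(self):
        with pytest.raises(ParameterError):
            weibull(-1.0, 5.5, 3.0, 0.5, 0.0)


class TestFitWeibull:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        x = np.geomspace(2.0, 16.0, 8)
        n = np.full(8, 2000)
        p = weibull(x, 5.5, 3.0, 0.5, 0.01)
        k = rng.binomial(n, p)
        fit = fit_weibull(x, n, k, gamma=0.5)
        assert fit.converged
        assert fit.alpha == pytest.approx(5.5, rel=0.05)
        assert fit.beta == pytest.approx(3.0, rel=0.35)

    def test_step_data_flags_pinned_slope(self):
        x = np.geomspace(1.0, 16.0, 8)
        n = np.full(8, 50)
        k = np.where(x < 5.0, 25, 50)  # perfect step around 5
        fit = fit_weibull(x, n, k, gamma=0.5)
        assert not fit.converged
        assert fit.beta > 40.0

    def test_refit_of_own_predictions_has_zero_deviance(self):
        x = np.geomspace(2.0, 16.0, 8)
        n = np.full(8, 1000.0)
        p = weibull(x, 5.5, 3.0, 0.5, 0.01)
        fit = fit_weibull(x, n, n * p, gamma=0.5)
        assert fit.deviance < 0.05

    def test_too_few_levels(self):
        with pytest.raises(ParameterError):
            fit_weibull([1.0, 2.0], [10, 10], [5, 8])

    def test_degenerate_data_flagged_not_raised(self):
        x = np.geomspace(2.0, 16.0, 8)
        n = np.full(8, 20)
        fit = fit_weibull(x, n, n, gamma=0.5)  # all successes
        assert not fit.converged


class TestMatchingFrequency:
    def test_symmetric_choice_data_centered_on_standard(self):
        rng = np.random.default_rng(1)
        x = np.log2(np.geomspace(1.9, 15.6, 8))
        n = np.full(8, 5000)
        beta, lam = 3.0, 0.0
        alpha = np.log2(5.5) / (-np.log(0.5)) ** (1 / beta)
        p = weibull(x, alpha, beta, 0.0, lam)
        fit = fit_weibull(x, n, rng.binomial(n, p), gamma=0.0, x_scale="log2")
        assert matching_frequency(fit) == pytest.approx(5.5, abs=0.05 * 5.5)

    def test_closed_form_matches_bisection(self):
        x = np.log2(np.geomspace(1.9, 15.6, 8))
        n = np.full(8, 500.0)
        p = weibull(x, 2.4, 4.0, 0.0, 0.02)
        fit = fit_weibull(x, n, n * p, gamma=0.0, x_scale="log2")
        pse = matching_frequency(fit)
        root = brentq(lambda xx: fit.predict(xx) - 0.5, x[0], x[-1], xtol=1e-12)
        assert np.log2(pse) == pytest.approx(root, abs=1e-6)

    def test_requires_choice_regime(self):
        x = np.geomspace(2.0, 16.0, 8)
        n = np.full(8, 100.0)
        fit = fit_weibull(x, n, n * weibull(x, 5.5, 3.0, 0.5, 0.0), gamma=0.5)
        with pytest.raises(ParameterError):
            matching_frequency(fit)


class TestThreshold:
    @pytest.fixture()
    def fit(self):
        x = np.geomspace(0.001, 0.4, 16)
        n = np.full(16, 1000.0)
        p = weibull(x, 0.1, 2.5, 0.5, 0.02)
        return fit_weibull(x, n, n * p, gamma=0.5)

    def test_round_trip_is_exact(self, fit):
        for level in (0.6, 0.75, 0.84, 0.9):
            t = threshold(fit, level)
            assert abs(fit.predict(t) - level) < 1e-10

    def test_matches_bisection(self, fit):
        t = threshold(fit, 0.75)
        root = brentq(lambda xx: fit.predict(xx) - 0.75, 1e-4, 1.0, xtol=1e-14)
        assert t == pytest.approx(root, abs=1e-6)

    def test_level_above_lapse_ceiling_rejected(self, fit):
        with pytest.raises(ParameterError):
            threshold(fit, 1.0 - fit.lamda / 2)
        with pytest.raises(ParameterError):
            threshold(fit, 0.4)


class TestBinomialCI:
    def test_large_n_interval(self):
        lo, hi = binomial_ci(0.845, 14400)
        assert (round(lo, 3), round(hi, 3)) == (0.839, 0.851)

    def test_small_n_width(self):
        lo, hi = binomial_ci(0.5, 4)
        assert lo < 0.5 < hi
        assert hi - lo == pytest.approx(2 * 1.96 * np.sqrt(0.25 / 4), abs=1e-3)

    def test_close_to_clopper_pearson_at_large_n(self):
        n, k = 14400, round(0.845 * 14400)
        lo, hi = binomial_ci(k / n, n)
        cp_lo = beta_dist.ppf(0.025, k, n - k + 1)
        cp_hi = beta_dist.ppf(0.975, k + 1, n - k)
        assert abs(lo - cp_lo) < 0.002 and abs(hi - cp_hi) < 0.002

    def test_invalid(self):
        with pytest.raises(ParameterError):
            binomial_ci(0.5, 0)


class TestParametricBootstrap:
    def test_zero_resamples_rejected(self):
        with pytest.raises(ParameterError):
            parametric_bootstrap(None, lambda f: 0.0, 0)

    def test_ci_self_consistency(self):
        # CIs from the fitted generator should usually contain the
        # generating location parameter
        rng = np.random.default_rng(3)
        x = np.geomspace(2.0, 16.0, 8)
        n = np.full(8, 400)
        p_true = weibull(x, 5.5, 3.0, 0.5, 0.01)
        hits = 0
        n_sim = 20
        for s in range(n_sim):
            k = rng.binomial(n, p_true)
            fit = fit_weibull(x, n, k, gamma=0.5)
            gen = WeibullBootstrapGenerator(fit)
            res = parametric_bootstrap(gen, lambda f: f.alpha, 99, seed=s)
            hits += res.ci_low <= 5.5 <= res.ci_high
        assert hits >= int(0.75 * n_sim)


class TestPseMonteCarloTest:
    def test_constructed_bias_detected(self):
        rng = np.random.default_rng(4)
        x = np.log2(np.geomspace(1.9, 15.6, 8))
        n = np.full(8, 400)
        beta = 3.0
        alpha = np.log2(3.8) / (-np.log(0.5)) ** (1 / beta)  # PSE at 3.8 c/deg
        k = rng.binomial(n, weibull(x, alpha, beta, 0.0, 0.0))
        res = pse_monte_carlo_test(x, n, k, standard_x=np.log2(5.5),
                                   n_resamples=99, seed=0, x_scale="log2")
        assert res["pse"] == pytest.approx(3.8, rel=0.1)
        assert res["p_value"] <= 0.02

    def test_null_data_give_large_p(self):
        rng = np.random.default_rng(5)
        x = np.log2(np.geomspace(1.9, 15.6, 8))
        n = np.full(8, 400)
        beta = 3.0
        alpha = np.log2(5.5) / (-np.log(0.5)) ** (1 / beta)
        big_p = 0
        for s in range(5):
            k = rng.binomial(n, weibull(x, alpha, beta, 0.0, 0.0))
            res = pse_monte_carlo_test(x, n, k, standard_x=np.log2(5.5),
                                       n_resamples=59, seed=s, x_scale="log2")
            big_p += res["p_value"] > 0.05
        assert big_p >= 4

    def test_constrained_fit_crosses_at_requested_pse(self):
        x = np.log2(np.geomspace(1.9, 15.6, 8))
        n = np.full(8, 300.0)
        p = weibull(x, 2.3, 3.5, 0.0, 0.01)
        fit = fit_weibull_fixed_pse(x, n, n * p, pse_x=np.log2(5.5))
        assert fit.predict(np.log2(5.5)) == pytest.approx(0.5, abs=1e-9)


class TestLearningRegression:
    def test_stationary_performance_not_flagged(self):
        rng = np.random.default_rng(6)
        flagged = 0
        for s in range(20):
            y = rng.random(1500) < 0.68
            res = learning_regression(y, subset_size=60, seed=s)
            flagged += res["p_value"] <= 0.05
        assert flagged <= 3

    def test_improvement_detected(self):
        rng = np.random.default_rng(7)
        blocks = [rng.random(60) < p for p in np.linspace(0.5, 0.9, 10)]
        y = np.concatenate(blocks)
        res = learning_regression(y, subset_size=60, seed=0)
        assert res["slope"] > 0
        assert res["p_value"] < 0.01

    def test_single_subset_rejected(self):
        with pytest.raises(ParameterError):
            learning_regression(np.ones(60), subset_size=60)


class TestDevianceScale:
    def test_well_specified_fit_deviance_is_chi_square_scaled(self):
        # deviance of a correctly specified fit should be of the order of
        # the residual degrees of freedom (8 levels - 3 parameters)
        rng = np.random.default_rng(8)
        x = np.geomspace(2.0, 16.0, 8)
        n = np.full(8, 200)
        devs = []
        for _ in range(10):
            k = rng.binomial(n, weibull(x, 5.5, 3.0, 0.5, 0.01))
            devs.append(fit_weibull(x, n, k, gamma=0.5).deviance)
        assert all(d >= 0 for d in devs)
        assert np.mean(devs) < 3 * (8 - 3)
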