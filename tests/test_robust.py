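"""Robust quasi-likelihood estimator: scores, weights, fits, quasi-deviance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import integrate, stats

from roblogit.glm import DesignMatrix, EstimationError, deviance_test, fit_irls
from roblogit.robust import (
    RobustConfig,
    expected_nu,
    expected_nu_antiderivative,
    fit_robust,
    huber_psi,
    leverage_weights,
    nu,
    nu_antiderivative,
    quasi_deviance_test,
    robust_or_ci,
)

C_GRID = [1.2, 1.345, 2.0]


class TestHuberPsi:
    def test_identity_inside_and_truncation_outside(self):
        assert huber_psi(0.5, 1.345) == 0.5
        assert huber_psi(2.0, 1.345) == 1.345
        assert huber_psi(-3.0, 1.345) == -1.345

    @settings(derandomize=True, max_examples=200)
    @given(st_h.floats(-50, 50), st_h.floats(0.1, 5.0))
    def test_odd_bounded_and_dominated(self, r, c):
        v = huber_psi(r, c)
        assert v == -huber_psi(-r, c)
        assert abs(v) <= min(abs(r), c) + 1e-12

    def test_continuous_at_truncation_point(self):
        c = 1.345
        assert huber_psi(c - 1e-12, c) == pytest.approx(huber_psi(c + 1e-12, c), abs=1e-10)


class TestLeverageWeights:
    def test_intercept_only_hat_values(self):
        X = DesignMatrix(np.ones((10, 1)), ["intercept"])
        w = leverage_weights(X)
        np.testing.assert_allclose(w, np.sqrt(0.9), rtol=1e-12)

    def test_hat_trace_equals_number_of_columns(self, rng):
        n, p = 40, 4
        M = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        X = DesignMatrix(M, [f"c{j}" for j in range(p)])
        h = 1.0 - leverage_weights(X) ** 2
        assert np.sum(h) == pytest.approx(p, rel=1e-10)

    def test_saturated_design_rejected(self):
        # n = p means every hat value is 1: weights would all vanish
        M = np.array([[1.0, 0.0], [1.0, 1.0]])
        with pytest.raises(EstimationError):
            DesignMatrix(M, ["intercept", "x"])


class TestNu:
    def test_hand_computed_values_at_half(self):
        assert nu(1, 0.5, 1.345) == pytest.approx(2.0, abs=1e-12)
        assert nu(0, 0.5, 1.345) == pytest.approx(-2.0, abs=1e-12)

    def test_untruncated_limit_is_quasi_score(self):
        for mu in (0.1, 0.35, 0.8):
            for y in (0, 1):
                expect = (y - mu) / (mu * (1 - mu))
                assert nu(y, mu, 1e9) == pytest.approx(expect, rel=1e-12)

    def test_boundary_mu_rejected(self):
        with pytest.raises(ValueError):
            nu(1, 0.0, 1.345)


class TestExpectedNu:
    def test_zero_when_nothing_truncated(self):
        assert expected_nu(0.5, 1.345) == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed_two_outcome_expectation(self):
        # mu=0.9: eps(1)=1/3 (kept), eps(0)=-3 (truncated to -1.345)
        # E[psi] = (1/3)(0.9) + (-1.345)(0.1) = 0.1655; E[nu] = 0.1655/0.3
        assert expected_nu(0.9, 1.345) == pytest.approx(0.5517, abs=1e-4)

    def test_vanishes_as_c_grows(self):
        for mu in (0.05, 0.3, 0.7, 0.97):
            assert expected_nu(mu, 1e9) == pytest.approx(0.0, abs=1e-9)

    def test_matches_quadrature_over_two_point_distribution(self):
        # independent route: integrate nu against the Bernoulli(mu) measure
        for mu in (0.12, 0.5, 0.83):
            direct = expected_nu(mu, 1.345)
            enum = nu(1, mu, 1.345) * mu + nu(0, mu, 1.345) * (1 - mu)
            assert direct == pytest.approx(enum, rel=1e-12)


class TestAntiderivatives:
    """Closed-form integrals of nu and E[nu] against adaptive quadrature."""

    @pytest.mark.parametrize("c", [0.8, 1.2, 1.345, 2.0])
    def test_nu_antiderivative_matches_quadrature(self, c, rng):
        for _ in range(5):
            a, b = np.sort(rng.uniform(0.01, 0.99, 2))
            for y in (0, 1):
                ref, _ = integrate.quad(lambda t: nu(y, t, c), a, b, limit=200)
                val = nu_antiderivative(y, b, c) - nu_antiderivative(y, a, c)
                assert val == pytest.approx(ref, abs=1e-8)

    @pytest.mark.parametrize("c", [0.8, 1.2, 1.345, 2.0])
    def test_expected_nu_antiderivative_matches_quadrature(self, c, rng):
        for _ in range(5):
            a, b = np.sort(rng.uniform(0.01, 0.99, 2))
            ref, _ = integrate.quad(lambda t: expected_nu(t, c), a, b, limit=200)
            val = expected_nu_antiderivative(b, c) - expected_nu_antiderivative(a, c)
            assert val == pytest.approx(ref, abs=1e-8)

    def test_anchored_at_the_roots(self):
        # nu(y, .) vanishes only at t = y; E[nu] vanishes at t = 1/2
        for c in C_GRID:
            assert nu_antiderivative(1, 1 - 1e-12, c) == pytest.approx(0.0, abs=1e-9)
            assert nu_antiderivative(0, 1e-12, c) == pytest.approx(0.0, abs=1e-9)
            assert expected_nu_antiderivative(0.5, c) == pytest.approx(0.0, abs=1e-14)


class TestFitRobust:
    def test_reduces_to_irls_for_huge_c(self, toy_design):
        # with w = 1: Huber truncation is the only departure from the MLE
        # (leverage weights are a separate, deliberate deviation)
        X, y = toy_design
        mle = fit_irls(X, y)
        rob = fit_robust(X, y, RobustConfig(c=1e6, use_leverage_weights=False))
        assert rob.converged
        np.testing.assert_allclose(rob.beta, mle.beta, atol=1e-6)

    @pytest.mark.parametrize("c", C_GRID)
    def test_estimating_equation_residual_small_at_convergence(self, toy_design, c):
        from roblogit.robust import _estimating_function

        X, y = toy_design
        fit = fit_robust(X, y, RobustConfig(c=c))
        assert fit.converged
        resid = _estimating_function(fit.beta, X.values, y, fit.leverage_w, c)
        assert np.max(np.abs(resid)) < 1e-6

    def test_invariant_to_observation_order(self, toy_design, rng):
        X, y = toy_design
        perm = rng.permutation(X.n)
        Xp = DesignMatrix(X.values[perm], list(X.column_names))
        f1 = fit_robust(X, y)
        f2 = fit_robust(Xp, y[perm])
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)

    def test_recovers_truth_on_clean_replicates(self):
        """Mean estimate within 3 Monte-Carlo SEs of the generating slope."""
        nrep, n, b0, b1 = 60, 500, -1.0, 0.08
        rng = np.random.default_rng(2024)
        a_, b_ = (20 - 52) / 15, (95 - 52) / 15
        slopes = []
        for _ in range(nrep):
            age = stats.truncnorm.rvs(a_, b_, loc=52, scale=15, size=n, random_state=rng)
            xc = age - 52
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(b0 + b1 * xc)))).astype(float)
            X = DesignMatrix(np.column_stack([np.ones(n), xc]), ["i", "age"])
            slopes.append(fit_robust(X, y).beta[1])
        slopes = np.array(slopes)
        mcse = slopes.std(ddof=1) / np.sqrt(nrep)
        assert abs(slopes.mean() - b1) < 3 * mcse

    @pytest.mark.parametrize("c", C_GRID)
    def test_less_biased_than_irls_under_extreme_age_mislabeling(self, c):
        """Label flips at both age extremes: robust slope closer to truth."""
        nrep, n, b0, b1 = 100, 500, -1.0, 0.08
        rng = np.random.default_rng(77)
        a_, b_ = (20 - 52) / 15, (95 - 52) / 15
        wins = 0
        for _ in range(nrep):
            age = stats.truncnorm.rvs(a_, b_, loc=52, scale=15, size=n, random_state=rng)
            xc = age - 52
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(b0 + b1 * xc)))).astype(float)
            order = np.argsort(xc)
            y[order[-5:]] = 0.0  # oldest 1% forced unaffected
            y[order[:5]] = 1.0  # youngest 1% forced affected
            X = DesignMatrix(np.column_stack([np.ones(n), xc]), ["i", "age"])
            bs = fit_irls(X, y).beta[1]
            br = fit_robust(X, y, RobustConfig(c=c)).beta[1]
            wins += abs(br - b1) < abs(bs - b1)
        assert wins >= 0.8 * nrep


class TestQuasiDeviance:
    def test_model_against_itself_is_zero(self, toy_design):
        X, y = toy_design
        fit = fit_robust(X, y)
        res = quasi_deviance_test(fit, fit)
        assert res.lambda_qm == pytest.approx(0.0, abs=1e-12)
        assert res.df == 0 and res.p_value == 1.0

    def test_reduces_to_classical_deviance_difference(self, rng):
        """c -> infinity, w = 1: Lambda_QM is the likelihood-ratio statistic."""
        n = 20
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.3 + x)))).astype(float)
        Xf = DesignMatrix(np.column_stack([np.ones(n), x]), ["intercept", "x"])
        Xr = DesignMatrix(np.ones((n, 1)), ["intercept"])
        cfg = RobustConfig(c=1e7, use_leverage_weights=False)
        res = quasi_deviance_test(fit_robust(Xf, y, cfg), fit_robust(Xr, y, cfg), cfg)
        stat, df, _ = deviance_test(fit_irls(Xf, y), fit_irls(Xr, y))
        assert res.df == df == 1
        assert res.lambda_qm == pytest.approx(stat, abs=1e-4)

    @pytest.mark.parametrize("c", C_GRID)
    def test_nonnegative_for_nested_fits(self, c, rng):
        for _ in range(5):
            n = 40
            x = rng.normal(size=n)
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.5 * x)))).astype(float)
            Xf = DesignMatrix(np.column_stack([np.ones(n), x]), ["intercept", "x"])
            Xr = DesignMatrix(np.ones((n, 1)), ["intercept"])
            cfg = RobustConfig(c=c)
            res = quasi_deviance_test(fit_robust(Xf, y, cfg), fit_robust(Xr, y, cfg), cfg)
            assert res.lambda_qm >= -1e-8

    def test_s_tilde_is_the_outcome_and_t_tilde_root_of_expected_nu(self, toy_design):
        X, y = toy_design
        fit = fit_robust(X, y)
        res = quasi_deviance_test(fit, fit)
        np.testing.assert_array_equal(res.s_tilde, y)
        for t in res.t_tilde:
            assert expected_nu(t, fit.config.c) == pytest.approx(0.0, abs=1e-12)


class TestRobustOrCi:
    def test_sandwich_matches_fisher_information_at_huge_c(self):
        rng = np.random.default_rng(9)
        n = 500
        a_, b_ = (20 - 52) / 15, (95 - 52) / 15
        age = stats.truncnorm.rvs(a_, b_, loc=52, scale=15, size=n, random_state=rng)
        xc = age - 52
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(-0.7 + 0.05 * xc)))).astype(float)
        X = DesignMatrix(np.column_stack([np.ones(n), xc]), ["i", "age"])
        se_rob = fit_robust(X, y, RobustConfig(c=1e6)).se()
        se_mle = fit_irls(X, y).se()
        assert np.max(np.abs(se_rob / se_mle - 1)) < 0.05

    def test_interval_centered_on_unit_odds_for_zero_coefficient(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        X = DesignMatrix(np.ones((20, 1)), ["intercept"])
        (_, orr, lo, hi) = robust_or_ci(fit_robust(X, y))[0]
        assert orr == pytest.approx(1.0, abs=1e-8)
        assert lo < 1.0 < hi
        assert np.log(hi) == pytest.approx(-np.log(lo), abs=1e-8)

    def test_interval_width_shrinks_at_root_n_rate(self):
        """Mean n=200 vs n=800 width ratio over seeds is ~ sqrt(4) = 2."""
        a_, b_ = (20 - 52) / 15, (95 - 52) / 15
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            age = stats.truncnorm.rvs(a_, b_, loc=52, scale=15, size=800, random_state=rng)
            xc = age - 52
            y = (rng.uniform(size=800) < 1 / (1 + np.exp(-(-0.7 + 0.05 * xc)))).astype(float)
            X800 = DesignMatrix(np.column_stack([np.ones(800), xc]), ["i", "age"])
            X200 = DesignMatrix(np.column_stack([np.ones(200), xc[:200]]), ["i", "age"])
            se8 = fit_robust(X800, y).se()
            se2 = fit_robust(X200, y[:200]).se()
            ratios.append(se2 / se8)
        mean_ratio = np.mean(ratios, axis=0)
        assert np.all(mean_ratio > 1.8) and np.all(mean_ratio < 2.2)
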