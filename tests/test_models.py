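"""Occupancy models: likelihoods, fits, expected distributions, CIs."""

import warnings

import numpy as np
import pytest
from scipy import stats

from occuhet import (
    DetectionHistory,
    expected_distribution,
    fit_basic,
    fit_model,
    fit_rn,
    fit_zibb,
    loglik_basic,
    simulate_betabinomial_history,
    simulate_rn_history,
    simulate_zib_history,
    wald_ci,
)
from occuhet.models import _betabinom_logpmf, loglik_rn, loglik_zibb
from occuhet.simulate import DegenerateHistoryError


def _history(y, z=None):
    return DetectionHistory(y=np.asarray(y, dtype=np.int8), z=z)


class TestLoglikBasic:
    def test_psi_one_equals_plain_binomial(self):
        D = np.array([0, 1, 2, 2])
        ll = loglik_basic(1.0, 0.3, D, 2)
        ref = stats.binom.logpmf(D, 2, 0.3).sum()
        assert ll == pytest.approx(ref)

    def test_total_probability_sums_to_one(self):
        # enumeration oracle: single site, N=2, all D configurations
        total = sum(np.exp(loglik_basic(0.35, 0.6, np.array([d]), 2))
                    for d in range(3))
        assert total == pytest.approx(1.0)

    def test_psi_zero_all_zero_history(self):
        assert loglik_basic(0.0, 0.5, np.zeros(5, dtype=int), 4) == 0.0

    def test_out_of_range_returns_neg_inf(self):
        D = np.array([1])
        assert loglik_basic(1.5, 0.5, D, 2) == -np.inf
        assert loglik_basic(0.5, -0.1, D, 2) == -np.inf


class TestFitBasic:
    def test_all_or_nothing_sites(self):
        # fraction f of sites always detected, rest never: psi=f, p=1
        y = np.zeros((10, 5), dtype=np.int8)
        y[:4] = 1
        fit = fit_basic(_history(y))
        assert fit.psi_hat == pytest.approx(0.4, abs=1e-3)
        assert fit.p_hat > 0.999

    def test_parameter_recovery_within_3se(self, rng):
        h = simulate_zib_history(0.6, 0.4, 2000, 10, rng)
        fit = fit_basic(h)
        assert fit.converged and fit.se_available
        logit = lambda x: np.log(x / (1 - x))
        assert abs(fit.params_transformed[0] - logit(0.6)) < 3 * fit.se_logit_psi
        assert abs(fit.params_transformed[1] - logit(0.4)) < 3 * fit.se_logit_p

    def test_degenerate_histories_rejected(self):
        with pytest.raises(DegenerateHistoryError):
            fit_basic(_history(np.zeros((5, 3))))
        with pytest.raises(DegenerateHistoryError):
            fit_basic(_history(np.ones((5, 3))))

    def test_likelihood_depends_only_on_counts(self, rng):
        h = simulate_zib_history(0.5, 0.5, 100, 6, rng)
        fit1 = fit_basic(h)
        # permute rows and shuffle each row's columns: D vector unchanged
        y = h.y[rng.permutation(100)]
        perm = np.argsort(rng.random(y.shape), axis=1)
        y = np.take_along_axis(y, perm, axis=1)
        fit2 = fit_basic(_history(y))
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)
        assert fit1.psi_hat == pytest.approx(fit2.psi_hat, abs=1e-5)


class TestFitZibb:
    def test_nests_basic_model(self, zib_history):
        # the binomial is the alpha+beta -> inf limit of the beta-binomial;
        # the approach is O(M N^2 / (alpha+beta)), so at double precision the
        # nested bound holds to ~1e-3 rather than exactly
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fb = fit_basic(zib_history)
            fz = fit_zibb(zib_history)
        assert fz.loglik >= fb.loglik - 1e-3

    def test_pmf_binomial_limit(self):
        # alpha = beta -> infinity with mean fixed reduces to Binomial(N, 1/2)
        bb = np.exp(_betabinom_logpmf(10, 1e6, 1e6))
        ref = stats.binom.pmf(np.arange(11), 10, 0.5)
        assert np.abs(bb - ref).max() < 1e-4

    def test_recovers_analytic_expected_frequencies(self):
        # fit to exact expected cell counts of psi=0.8, Beta(0.4, 0.4), N=10
        pmf = np.exp(_betabinom_logpmf(10, 0.4, 0.4))
        counts = 200 * (0.8 * pmf + 0.2 * np.eye(11)[0])
        fit = fit_zibb(counts)
        assert fit.psi_hat == pytest.approx(0.8, abs=1e-3)
        assert fit.alpha_hat == pytest.approx(0.4, abs=1e-2)
        assert fit.beta_hat == pytest.approx(0.4, abs=1e-2)

    def test_parameter_recovery_within_3se(self, rng):
        h = simulate_betabinomial_history(0.6, 0.5, 0.7, 2000, 20, rng)
        fit = fit_zibb(h)
        assert fit.converged and fit.se_available
        truth = [np.log(0.6 / 0.4), np.log(0.5), np.log(0.7)]
        for est, se, tr in zip(fit.params_transformed, fit.se_transformed, truth):
            assert abs(est - tr) < 3 * se

    def test_two_visit_warning(self, rng):
        h = simulate_betabinomial_history(0.7, 0.4, 0.4, 100, 2, rng)
        with pytest.warns(RuntimeWarning, match="weakly identified"):
            fit_zibb(h)

    def test_boundary_flag(self, rng):
        # nearly saturated detections drive psi to the boundary
        y = np.ones((50, 6), dtype=np.int8)
        y[0, 0] = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_zibb(_history(y))
        assert fit.psi_hat > 0.99 and fit.boundary


class TestFitRN:
    def test_derived_occupancy_identity(self, rng):
        h = simulate_rn_history(1.2, 0.2, 400, 10, rng)
        fit = fit_rn(h)
        assert fit.psi_hat == -np.expm1(-fit.lambda_hat)

    def test_truncation_stability(self, rng):
        h = simulate_rn_history(1.0, 0.25, 400, 10, rng)
        fit = fit_rn(h)
        ll_k = loglik_rn(fit.lambda_hat, fit.r_hat, h.D, 10, fit.K)
        ll_2k = loglik_rn(fit.lambda_hat, fit.r_hat, h.D, 10, 2 * fit.K)
        assert abs(ll_k - ll_2k) < 1e-6

    def test_auto_doubles_small_K(self, rng):
        h = simulate_rn_history(3.0, 0.1, 300, 10, rng)
        with pytest.warns(RuntimeWarning, match="doubling K"):
            fit = fit_rn(h, K=4)
        assert fit.K > 4
        assert stats.poisson.sf(fit.K, fit.lambda_hat) <= 1e-8

    def test_parameter_recovery_within_3se(self, rng):
        h = simulate_rn_history(1.0, 0.25, 2000, 20, rng)
        fit = fit_rn(h)
        assert fit.converged and fit.se_available
        truth = [np.log(1.0), np.log(0.25 / 0.75)]
        for est, se, tr in zip(fit.params_transformed, fit.se_transformed, truth):
            assert abs(est - tr) < 3 * se

    def test_invalid_K(self, zib_history):
        with pytest.raises(ValueError):
            fit_rn(zib_history, K=0)


class TestExpectedDistribution:
    def test_basic_binomial_cells(self):
        # psi=1, p=0.5, N=2, M=4 -> (1, 2, 1)
        y = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        fit = fit_basic(_history(y))
        e = expected_distribution(fit, 4, 2)
        assert e == pytest.approx([1, 2, 1], abs=0.05)
        assert e.sum() == pytest.approx(4, abs=1e-6)

    def test_rn_matches_poisson_binomial_enumeration(self, rng):
        h = simulate_rn_history(0.8, 0.3, 300, 6, rng)
        fit = fit_rn(h)
        # independent enumeration of the Poisson-mixture pmf
        lam, r, K = fit.lambda_hat, fit.r_hat, fit.K
        pmf = np.zeros(7)
        for b in range(K + 1):
            p = 1 - (1 - r) ** b
            pmf += stats.poisson.pmf(b, lam) * stats.binom.pmf(np.arange(7), 6, p)
        pmf /= pmf.sum()
        assert expected_distribution(fit, 300, 6) == pytest.approx(
            300 * pmf, abs=1e-6)

    def test_zibb_uniform_under_beta11(self):
        # Beta(1,1) detection heterogeneity makes D uniform on 0..N
        pmf = np.exp(_betabinom_logpmf(8, 1.0, 1.0))
        assert pmf == pytest.approx(np.full(9, 1 / 9), abs=1e-12)

    def test_zibb_cell_probabilities_are_mixture(self):
        ll = loglik_zibb(0.7, 2.0, 3.0, np.array([0]), 4)
        # manual mixture: (1-psi) + psi * BetaBinom(0; 4, 2, 3)
        from scipy.special import betaln, comb
        bb0 = comb(4, 0) * np.exp(betaln(2.0, 7.0) - betaln(2.0, 3.0))
        assert np.exp(ll) == pytest.approx(0.3 + 0.7 * bb0)


class TestWaldCI:
    def test_ordering_and_range(self, zib_history):
        fit = fit_basic(zib_history)
        lo, hi = wald_ci(fit)
        assert 0.0 <= lo <= fit.psi_hat <= hi <= 1.0

    def test_rn_interval_monotone_transform(self, rng):
        h = simulate_rn_history(1.0, 0.3, 500, 10, rng)
        fit = fit_rn(h)
        lo, hi = wald_ci(fit)
        assert 0.0 <= lo <= fit.psi_hat <= hi <= 1.0

    def test_unavailable_se_returns_none(self, zib_history):
        fit = fit_basic(zib_history)
        fit.se_transformed = np.array([np.nan, np.nan])
        assert wald_ci(fit) is None


def test_fit_model_dispatch_and_unknown_name(zib_history):
    assert fit_model("basic", zib_history).model == "basic"
    with pytest.raises(ValueError, match="unknown model"):
        fit_model("bayes", zib_history)
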