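"""Gibbs sampler: conjugate block oracles, PSR diagnostics, posterior checks."""

import numpy as np
import pytest

from crtmediate import TrialDesign, generate_trial
from crtmediate.bayes_estimator import (
    MCMCDraws,
    PARAM_NAMES,
    IDX,
    N_STORE,
    PriorConfig,
    _draw_coef_block,
    _draw_invgamma,
    _draw_invwishart2,
    psr,
    run_mcmc,
    run_mcmc_batch,
    summarize_indirect,
)
from crtmediate.ml_estimator import fit_ml


class TestPsr:
    def test_identical_chains(self, rng):
        x = rng.standard_normal(200)
        chains = np.tile(x, (4, 1))
        val = psr(chains)
        assert val == pytest.approx(np.sqrt(99 / 100))  # second half length 100
        assert val <= 1.0

    def test_well_mixed_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 100_000))
        assert abs(psr(chains) - 1.0) < 0.01

    def test_disjoint_chains_diverge(self, rng):
        chains = rng.standard_normal((2, 5000))
        chains[1] += 10.0
        assert psr(chains) > 1.1 * 5  # far above any convergence threshold

    def test_zero_within_variance(self):
        chains = np.array([[1.0] * 8, [2.0] * 8])
        assert psr(chains) == np.inf
        const = np.ones((3, 8))
        assert psr(const) <= 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            psr(np.zeros((1, 100)))


class TestConjugateOracles:
    """Block samplers against closed-form flat-prior posteriors."""

    def test_coefficient_block_matches_ols_posterior(self, rng):
        """Under a flat prior and known sigma^2 the coefficient draw is
        N(beta_ols, sigma^2 (X'X)^-1)."""
        n, k = 60, 2
        X = rng.standard_normal((n, k))
        beta = np.array([0.7, -0.3])
        sigma2 = 1.3
        y = X @ beta + rng.normal(0, np.sqrt(sigma2), n)
        XtX, Xty = X.T @ X, X.T @ y
        beta_ols = np.linalg.solve(XtX, Xty)
        target_cov = sigma2 * np.linalg.inv(XtX)
        R = 40_000
        prec = np.broadcast_to(XtX / sigma2, (R, k, k)).copy()
        rhs = np.broadcast_to(Xty / sigma2, (R, k)).copy()
        draws = _draw_coef_block(rng, prec, rhs, np.zeros((R, k)), PriorConfig())
        se_mean = np.sqrt(np.diag(target_cov) / R)
        assert np.all(np.abs(draws.mean(axis=0) - beta_ols) < 4 * se_mean)
        assert np.cov(draws.T) == pytest.approx(target_cov, rel=0.05, abs=5e-4)

    def test_variance_draw_matches_inverse_gamma_posterior(self, rng):
        """IG(-1, 0) prior: sigma^2 | data ~ IG(n/2 - 1, SSE/2), whose mean
        is SSE / (n - 4)."""
        n, sse = 40, 55.0
        draws = _draw_invgamma(rng, n / 2 - 1.0, np.full(100_000, sse / 2))
        assert draws.mean() == pytest.approx(sse / (n - 4), rel=0.02)
        with pytest.raises(ValueError):
            _draw_invgamma(rng, -0.5, np.ones(3))

    def test_invwishart_block_matches_flat_posterior_mean(self, rng):
        """Flat prior on a 2x2 covariance: posterior IW(n-3, S) with mean
        S / (n - 6)."""
        n = 200
        S = np.array([[4.0, 1.2], [1.2, 2.5]])
        scale = np.broadcast_to(S, (50_000, 2, 2)).copy()
        draws = _draw_invwishart2(rng, n - 3.0, scale)
        assert draws.mean(axis=0) == pytest.approx(S / (n - 6), rel=0.03)
        with pytest.raises(ValueError):
            _draw_invwishart2(rng, 1.0, scale[:2])

    def test_posterior_medians_track_ml_on_large_data(self):
        """With flat priors and lots of information the posterior medians
        agree with the ML estimates (asymptotic likelihood dominance)."""
        df = generate_trial(TrialDesign(300, 10), seed=5)
        draws = run_mcmc(df, seed=17)
        assert draws.converged
        fit = fit_ml(df)
        for nm in ("a_B", "b_B", "c_B", "b_W", "g_W", "c_W",
                   "var_att_W", "var_int_B", "var_beh_B"):
            med = np.median(draws.draws(nm))
            psd = draws.draws(nm).std(ddof=1)
            assert abs(med - fit.param(nm)) < max(0.25 * psd, 0.01), nm


class TestSampler:
    def test_deterministic_given_seed(self):
        df = generate_trial(TrialDesign(10, 5), seed=1)
        d1 = run_mcmc(df, seed=9, min_iter=400)
        d2 = run_mcmc(df, seed=9, min_iter=400)
        np.testing.assert_array_equal(d1.chains, d2.chains)

    def test_indirect_draw_is_exact_product(self):
        df = generate_trial(TrialDesign(10, 5), seed=2)
        d = run_mcmc(df, seed=4, min_iter=300, max_iter=600)
        prod = (
            d.chains[:, :, IDX["a_B"]]
            * d.chains[:, :, IDX["b_B"]]
            * d.chains[:, :, IDX["c_B"]]
        )
        np.testing.assert_array_equal(prod, d.chains[:, :, IDX["indirect"]])

    def test_protocol_shape(self):
        df = generate_trial(TrialDesign(10, 5), seed=3)
        d = run_mcmc(df, seed=11, min_iter=5000)
        assert d.chains.shape[0] == 4
        assert d.n_iter >= 5000
        assert d.n_burn == d.n_iter // 2
        assert d.n_iter - d.n_burn >= 2500
        assert set(d.psr_trace) >= {"a_B", "b_B", "c_B", "indirect", "var_int_B"}

    def test_nonconvergence_reported_at_max_iter(self):
        df = generate_trial(TrialDesign(5, 5), seed=6)
        d = run_mcmc(df, seed=2, min_iter=200, max_iter=300, psr_threshold=1.0001)
        assert not d.converged
        assert d.n_iter == 300

    def test_batch_requires_common_design(self):
        a = generate_trial(TrialDesign(5, 5), seed=1)
        b = generate_trial(TrialDesign(5, 10), seed=1)
        with pytest.raises(ValueError, match="common design"):
            run_mcmc_batch([a, b], min_iter=10)

    def test_uniform_prior_knob_runs(self):
        df = generate_trial(TrialDesign(5, 5), seed=9)
        priors = PriorConfig(coef_prior="uniform", coef_bounds=(-2.0, 2.0))
        d = run_mcmc(df, priors=priors, seed=1, min_iter=200, max_iter=400)
        for nm in ("a_B", "b_B", "c_B", "b_W"):
            x = d.chains[:, :, IDX[nm]]
            assert np.all(x >= -2.0) and np.all(x <= 2.0)


class TestSummaries:
    def test_degenerate_draws(self):
        chains = np.full((4, 100, N_STORE), 0.125)
        d = MCMCDraws(
            chains=chains, param_names=PARAM_NAMES, n_burn=50,
            psr_trace={}, converged=True, n_iter=100,
        )
        res = summarize_indirect(d)
        assert res.median == pytest.approx(0.125)
        assert (res.ci_low, res.ci_high) == (pytest.approx(0.125), pytest.approx(0.125))
        assert res.significant

    def test_symmetric_draws_around_zero_not_significant(self, rng):
        chains = np.zeros((4, 2000, N_STORE))
        x = rng.standard_normal((4, 1000))
        chains[:, 1000:, IDX["indirect"]] = x
        d = MCMCDraws(
            chains=chains, param_names=PARAM_NAMES, n_burn=1000,
            psr_trace={}, converged=True, n_iter=2000,
        )
        assert not summarize_indirect(d).significant

    def test_aborted_run_has_no_summary(self):
        d = MCMCDraws(
            chains=np.empty((4, 0, N_STORE)), param_names=PARAM_NAMES,
            n_burn=0, psr_trace={}, converged=False, n_iter=0,
        )
        with pytest.raises(ValueError, match="no draws"):
            summarize_indirect(d)
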