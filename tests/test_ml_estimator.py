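"""ML estimator: likelihood oracle, inference, convergence classification."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from crtmediate import (
    PathModelParams,
    TrialDesign,
    generate_trial,
    implied_moments,
)
from crtmediate.ml_estimator import (
    IDX,
    MLFit,
    N_PARAMS,
    PARAM_NAMES,
    classify_fit,
    fit_ml,
    ml_inference,
    neg2_loglik,
    sufficient_stats,
)
from conftest import rep_seeds


def dense_neg2ll(df, params):
    """Brute-force -2 log likelihood through the stacked 4n-dimensional
    Gaussian of each cluster (oracle, no balanced-data decomposition)."""
    mo = implied_moments(params)
    total = 0.0
    for _, grp in df.groupby("cluster"):
        y = grp[["attitude", "norms", "intention", "behavior"]].to_numpy().ravel()
        n = len(grp)
        t = grp["treatment"].iloc[0]
        mean = np.tile(mo.delta * t, n)
        V = np.kron(np.eye(n), mo.sigma_W) + np.kron(np.ones((n, n)), mo.sigma_B)
        total += -2.0 * multivariate_normal.logpdf(y, mean, V)
    return total


PARAM_VARIANTS = [
    PathModelParams(),
    PathModelParams(a_B=0.0, b_W=0.0, b_B=0.0, g_W=0.0, g_B=0.0, c_W=0.0, c_B=0.0),
    PathModelParams(a_B=0.9, b_B=0.2, c_W=0.8, var_int_W=0.6, cov_attnorm_B=-0.4),
    PathModelParams(var_att_W=1.1, var_att_B=2.2, var_beh_B=0.1, g_W=-0.5),
]


class TestLikelihood:
    @pytest.mark.parametrize("design", [(2, 2), (6, 5)])
    @pytest.mark.parametrize("params", PARAM_VARIANTS)
    def test_matches_dense_gaussian_oracle(self, design, params):
        """Balanced-data factorization equals the dense multivariate-normal
        evaluation, constant included, to 1e-8."""
        df = generate_trial(TrialDesign(*design), seed=13)
        assert neg2_loglik(df, params) == pytest.approx(
            dense_neg2ll(df, params), abs=1e-8
        )

    def test_invariant_to_row_and_cluster_permutations(self, rng, default_params):
        df = generate_trial(TrialDesign(5, 4), seed=3)
        ref = neg2_loglik(df, default_params)
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert neg2_loglik(shuffled, default_params) == pytest.approx(ref, rel=1e-12)
        relabel = df.copy()
        perm = rng.permutation(df["cluster"].nunique())
        relabel["cluster"] = perm[relabel["cluster"].to_numpy()]
        assert neg2_loglik(relabel, default_params) == pytest.approx(ref, rel=1e-12)

    def test_true_params_beat_perturbed_params(self, default_params):
        """At a decent sample size the likelihood at the truth dominates a
        +0.3 perturbation of every coefficient (consistency)."""
        worse = default_params.with_updates(
            **{k: getattr(default_params, k) + 0.3
               for k in ("a_B", "b_W", "b_B", "g_W", "g_B", "c_W", "c_B")}
        )
        wins = sum(
            neg2_loglik(df := generate_trial(TrialDesign(50, 10), seed=s), default_params)
            < neg2_loglik(df, worse)
            for s in rep_seeds(31, 30)
        )
        assert wins == 30

    def test_nonpositive_definite_params_give_inf(self, default_params):
        df = generate_trial(TrialDesign(3, 3), seed=5)
        bad = default_params.with_updates(var_att_W=-3.0)
        assert neg2_loglik(df, bad) == np.inf


class TestFit:
    def test_parameter_recovery(self, default_params):
        """Mean estimate of every free parameter across replications falls
        within 3.5 MC-SEs of its population value at a large design."""
        thetas = []
        for s in rep_seeds(1234, 100):
            fit = fit_ml(generate_trial(TrialDesign(200, 10), seed=s))
            assert fit.status == "converged"
            thetas.append(fit.theta_hat)
        thetas = np.asarray(thetas)
        truth = np.zeros(N_PARAMS)
        for name, value in default_params.as_dict().items():
            truth[IDX[name]] = value
        se = thetas.std(axis=0, ddof=1) / np.sqrt(len(thetas))
        err = np.abs(thetas.mean(axis=0) - truth)
        assert np.all(err < 3.5 * se), dict(
            zip(PARAM_NAMES, np.round(err / se, 2))
        )

    def test_one_cluster_per_condition_fails_gracefully(self):
        df = generate_trial(TrialDesign(2, 4), seed=0)
        df = df[df["cluster"].isin([0, 1])]  # one treated, one control left
        fit = fit_ml(df)
        assert fit.status == "failed"
        assert "2 clusters per condition" in fit.message

    def test_deterministic(self):
        df = generate_trial(TrialDesign(10, 5), seed=42)
        f1, f2 = fit_ml(df), fit_ml(df)
        np.testing.assert_array_equal(f1.theta_hat, f2.theta_hat)


class TestInference:
    def test_degenerate_variance(self):
        fit = MLFit(
            theta_hat=_theta(a_B=0.5, b_B=0.5, c_B=0.5),
            vcov=np.zeros((N_PARAMS, N_PARAMS)),
            neg2loglik=0.0, status="converged",
        )
        inf = ml_inference(fit)
        assert inf.estimate == pytest.approx(0.125)
        assert inf.se == 0.0
        assert inf.significant

    def test_hand_computed_delta_method_se(self):
        """V = diag(0.04) on (a, b, c) at 0.5 each:
        se = sqrt(3 * 0.25 * 0.25 * 0.04) = 0.0866."""
        vcov = np.zeros((N_PARAMS, N_PARAMS))
        for nm in ("a_B", "b_B", "c_B"):
            vcov[IDX[nm], IDX[nm]] = 0.04
        fit = MLFit(
            theta_hat=_theta(a_B=0.5, b_B=0.5, c_B=0.5),
            vcov=vcov, neg2loglik=0.0, status="converged",
        )
        inf = ml_inference(fit)
        assert inf.se == pytest.approx(0.0866, abs=1e-4)
        assert inf.ci_low == pytest.approx(0.125 - 1.96 * inf.se)
        assert not inf.significant

    def test_delta_se_tracks_product_of_normals_simulation(self, rng):
        """First-order delta SE within 10% of the Monte Carlo SD of the
        product of three independent N(0.5, 0.04) draws."""
        draws = rng.normal(0.5, 0.2, size=(3, 100_000)).prod(axis=0)
        assert abs(0.0866 / draws.std(ddof=1) - 1.0) < 0.10

    def test_missing_vcov_propagates(self):
        fit = MLFit(
            theta_hat=_theta(), vcov=None, neg2loglik=0.0,
            status="converged", warnings={"SE_FAIL"},
        )
        with pytest.raises(ValueError, match="SE_FAIL"):
            ml_inference(fit)


class TestClassification:
    def test_clean_fit_is_complete(self):
        fit = MLFit(
            theta_hat=_theta(), vcov=np.eye(N_PARAMS),
            neg2loglik=10.0, status="converged",
        )
        cls = classify_fit(fit)
        assert cls.complete and not cls.warning_types

    def test_negative_variance_is_flagged_but_complete(self):
        fit = MLFit(
            theta_hat=_theta(var_int_B=-0.2), vcov=np.eye(N_PARAMS),
            neg2loglik=10.0, status="converged", warnings={"NEG_VARIANCE"},
        )
        cls = classify_fit(fit)
        assert cls.complete
        assert "NEG_VARIANCE" in cls.warning_types

    def test_se_failure_is_incomplete(self):
        fit = MLFit(
            theta_hat=_theta(), vcov=None, neg2loglik=10.0,
            status="converged", warnings={"SE_FAIL"},
        )
        assert not classify_fit(fit).complete

    def test_small_designs_produce_inadmissible_and_incomplete_runs(self):
        """With 5 clusters per condition the optimizer frequently lands on
        negative between-level variances or unusable information matrices."""
        n_problem = 0
        for s in rep_seeds(77, 25):
            fit = fit_ml(generate_trial(TrialDesign(5, 5), seed=s))
            cls = classify_fit(fit)
            if not cls.complete or cls.warning_types:
                n_problem += 1
        assert n_problem >= 5


def _theta(**overrides):
    theta = np.zeros(N_PARAMS)
    defaults = PathModelParams().as_dict()
    for name in PARAM_NAMES:
        theta[IDX[name]] = overrides.get(name, defaults.get(name, 0.0))
    return theta
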