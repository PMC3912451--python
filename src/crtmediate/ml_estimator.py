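"""Full maximum-likelihood estimation of the two-level path model.

The Gaussian likelihood for a balanced cluster of size n has joint
covariance V = I_n (x) Sigma_W + J_n (x) Sigma_B and mean mu(T_j) repeated
over members.  It factorizes into an (n-1)-weighted within term on Sigma_W
(driven by the pooled within-cluster scatter) and a cluster-mean term on
Sigma_n = Sigma_W + n*Sigma_B, which is what ``neg2_loglik`` evaluates; the
value equals the dense 4n-dimensional Gaussian evaluation including the
2*pi constant.

Variances are deliberately parameterized *unconstrained* (no log transform)
so the optimizer can land on negative variance estimates and non-positive-
definite level covariance matrices — inadmissible solutions are a finding
to be counted, not an error to be prevented.  Inference on the indirect
effect a*b*c uses the multivariate delta method on the between-level
coefficient block of the inverted observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize

from .model_core import ATT, BEH, INT, NORM, PathModelParams, indirect_effect

__all__ = [
    "PARAM_NAMES",
    "SufficientStats",
    "MLFit",
    "MLInference",
    "FitClassification",
    "sufficient_stats",
    "neg2_loglik",
    "fit_ml",
    "ml_inference",
    "classify_fit",
]

# free parameters of the two-level model, in optimizer order:
# 8 within (coefficients, exogenous block, residual variances),
# 13 between (coefficients, intercepts/means, exogenous block, residuals)
PARAM_NAMES = (
    "b_W", "g_W", "c_W",
    "var_att_W", "var_norm_W", "cov_attnorm_W", "var_int_W", "var_beh_W",
    "a_B", "b_B", "g_B", "c_B",
    "nu_att", "nu_norm", "nu_int", "nu_beh",
    "var_att_B", "var_norm_B", "cov_attnorm_B", "var_int_B", "var_beh_B",
)
IDX = {name: i for i, name in enumerate(PARAM_NAMES)}
N_PARAMS = len(PARAM_NAMES)

_VARIANCE_NAMES = tuple(n for n in PARAM_NAMES if n.startswith("var_"))
_ABC = ("a_B", "b_B", "c_B")

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class SufficientStats:
    """Balanced-design sufficient statistics for the two-level likelihood."""

    n: int                  # cluster size
    J: int                  # number of clusters
    J_arm: np.ndarray       # clusters per arm, shape (2,)
    sum_ybar: np.ndarray    # per-arm sum of cluster means, (2, 4)
    ss_ybar: np.ndarray     # per-arm sum of ybar ybar', (2, 4, 4)
    S_within: np.ndarray    # pooled within-cluster scatter, (4, 4)

    @property
    def M(self) -> int:
        return self.n * self.J


def sufficient_stats(data: pd.DataFrame) -> SufficientStats:
    """Reduce a balanced trial dataset to its likelihood sufficient stats."""
    y = data[["attitude", "norms", "intention", "behavior"]].to_numpy()
    clusters, inv = np.unique(data["cluster"].to_numpy(), return_inverse=True)
    J = len(clusters)
    counts = np.bincount(inv, minlength=J)
    if counts.min() != counts.max():
        raise ValueError("dataset is not balanced: unequal cluster sizes")
    n = int(counts[0])
    ybar = np.zeros((J, 4))
    for k in range(4):
        ybar[:, k] = np.bincount(inv, weights=y[:, k], minlength=J) / n
    resid = y - ybar[inv]
    S_within = resid.T @ resid
    treat = np.zeros(J, dtype=int)
    np.maximum.at(treat, inv, data["treatment"].to_numpy().astype(int))
    J_arm = np.array([(treat == 0).sum(), (treat == 1).sum()])
    sum_ybar = np.zeros((2, 4))
    ss_ybar = np.zeros((2, 4, 4))
    for g in (0, 1):
        yb = ybar[treat == g]
        sum_ybar[g] = yb.sum(axis=0)
        ss_ybar[g] = yb.T @ yb
    return SufficientStats(
        n=n, J=J, J_arm=J_arm, sum_ybar=sum_ybar, ss_ybar=ss_ybar, S_within=S_within
    )


def _batch_moments(thetas: np.ndarray):
    """Sigma_W, Sigma_B and the two arm means for a (K, 21) parameter batch."""
    K = thetas.shape[0]
    eye = np.broadcast_to(np.eye(4), (K, 4, 4)).copy()

    def _level(level: str):
        b = thetas[:, IDX[f"b_{level}"]]
        g = thetas[:, IDX[f"g_{level}"]]
        c = thetas[:, IDX[f"c_{level}"]]
        A = eye.copy()  # (I - B)^-1 in closed form; B strictly lower triangular
        A[:, INT, ATT] = b
        A[:, INT, NORM] = g
        A[:, BEH, INT] = c
        A[:, BEH, ATT] = c * b
        A[:, BEH, NORM] = c * g
        Psi = np.zeros((K, 4, 4))
        Psi[:, ATT, ATT] = thetas[:, IDX[f"var_att_{level}"]]
        Psi[:, NORM, NORM] = thetas[:, IDX[f"var_norm_{level}"]]
        cov = thetas[:, IDX[f"cov_attnorm_{level}"]]
        Psi[:, ATT, NORM] = Psi[:, NORM, ATT] = cov
        Psi[:, INT, INT] = thetas[:, IDX[f"var_int_{level}"]]
        Psi[:, BEH, BEH] = thetas[:, IDX[f"var_beh_{level}"]]
        return A, A @ Psi @ A.transpose(0, 2, 1)

    _, sigma_W = _level("W")
    A_B, sigma_B = _level("B")
    nu = thetas[:, [IDX["nu_att"], IDX["nu_norm"], IDX["nu_int"], IDX["nu_beh"]]]
    m0 = np.einsum("kij,kj->ki", A_B, nu)
    nu1 = nu.copy()
    nu1[:, ATT] += thetas[:, IDX["a_B"]]
    m1 = np.einsum("kij,kj->ki", A_B, nu1)
    return sigma_W, sigma_B, m0, m1


def _batch_neg2ll(thetas: np.ndarray, stats: SufficientStats) -> np.ndarray:
    """-2 log likelihood for a batch of parameter vectors; +inf outside the
    positive-definite region (optimizer-safe)."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    K = thetas.shape[0]
    values = np.full(K, np.inf)
    finite = np.all(np.isfinite(thetas), axis=1)
    if not finite.any():
        return values
    sigma_W, sigma_B, m0, m1 = _batch_moments(thetas[finite])
    n, J = stats.n, stats.J
    sigma_n = sigma_W + n * sigma_B
    # positive-definite screen on both covariance factors of the likelihood
    ok = np.linalg.eigvalsh(sigma_W)[:, 0] > 0
    ok &= np.linalg.eigvalsh(sigma_n)[:, 0] > 0
    if not ok.any():
        return values
    sigma_W, sigma_n = sigma_W[ok], sigma_n[ok]
    m0, m1 = m0[ok], m1[ok]
    ld_W = np.linalg.slogdet(sigma_W)[1]
    ld_N = np.linalg.slogdet(sigma_n)[1]
    inv_W = np.linalg.inv(sigma_W)
    inv_N = np.linalg.inv(sigma_n)
    # within term: sum_j [(n-1) log|S_W| + tr(S_W^-1 S_j)]
    v = J * (n - 1) * ld_W + np.einsum("kij,ij->k", inv_W, stats.S_within)
    # between term: sum_j [log|S_n| + n (ybar_j - m)' S_n^-1 (ybar_j - m)]
    v += J * ld_N
    for g, m in ((0, m0), (1, m1)):
        quad = (
            np.einsum("kij,ij->k", inv_N, stats.ss_ybar[g])
            - 2.0 * np.einsum("ki,kij,j->k", m, inv_N, stats.sum_ybar[g])
            + stats.J_arm[g] * np.einsum("ki,kij,kj->k", m, inv_N, m)
        )
        v += n * quad
    v += 4.0 * stats.M * _LOG_2PI
    out = np.full(int(finite.sum()), np.inf)
    out[ok] = v
    values[finite] = out
    return values


def _neg2ll(theta: np.ndarray, stats: SufficientStats) -> float:
    return float(_batch_neg2ll(np.asarray(theta)[None, :], stats)[0])


def _params_to_theta(params: PathModelParams) -> np.ndarray:
    theta = np.zeros(N_PARAMS)
    for name, value in params.as_dict().items():
        theta[IDX[name]] = value
    return theta  # intercepts stay at their population value 0


def _theta_to_params(theta: np.ndarray) -> PathModelParams:
    d = {
        name: float(theta[IDX[name]])
        for name in PARAM_NAMES
        if not name.startswith("nu_")
    }
    return PathModelParams(**d)  # type: ignore[arg-type]


def neg2_loglik(data: pd.DataFrame, params: PathModelParams) -> float:
    """-2 log likelihood of a balanced dataset at the given parameters.

    Intercepts are fixed at their population value zero (control means are
    zero by construction); for the free-intercept likelihood used in
    fitting, see :func:`fit_ml`.
    """
    return _neg2ll(_params_to_theta(params), sufficient_stats(data))


def moment_start(stats: SufficientStats) -> np.ndarray:
    """Deterministic moment-based starting values.

    Within parameters come from pooled-within moment regressions; between
    parameters from cluster-mean moments with the Sigma_W/n correction and
    floored variances.  Falls back to generic values on degenerate moments.
    """
    n, J = stats.n, stats.J
    theta = np.zeros(N_PARAMS)
    S_W = stats.S_within / max(stats.M - J, 1)
    mbar = stats.sum_ybar / stats.J_arm[:, None]
    S_bet_raw = np.zeros((4, 4))
    for g in (0, 1):
        S_bet_raw += stats.ss_ybar[g] - stats.J_arm[g] * np.outer(mbar[g], mbar[g])
    S_bet = S_bet_raw / max(J - 2, 1)
    S_B = S_bet - S_W / n
    floor = 0.05
    for k in range(4):
        S_B[k, k] = max(S_B[k, k], floor)

    def _fill(level: str, S: np.ndarray) -> None:
        try:
            bg = np.linalg.solve(S[:2, :2], S[:2, INT])
        except np.linalg.LinAlgError:
            bg = np.array([0.3, 0.3])
        v_int = max(S[INT, INT] - bg @ S[:2, INT], floor)
        c = S[INT, BEH] / S[INT, INT] if S[INT, INT] > floor else 0.3
        v_beh = max(S[BEH, BEH] - c * S[INT, BEH], floor)
        cov = np.clip(
            S[ATT, NORM],
            -0.95 * np.sqrt(S[ATT, ATT] * S[NORM, NORM]),
            0.95 * np.sqrt(S[ATT, ATT] * S[NORM, NORM]),
        )
        theta[IDX[f"b_{level}"]] = bg[0]
        theta[IDX[f"g_{level}"]] = bg[1]
        theta[IDX[f"c_{level}"]] = c
        theta[IDX[f"var_att_{level}"]] = max(S[ATT, ATT], floor)
        theta[IDX[f"var_norm_{level}"]] = max(S[NORM, NORM], floor)
        theta[IDX[f"cov_attnorm_{level}"]] = cov
        theta[IDX[f"var_int_{level}"]] = v_int
        theta[IDX[f"var_beh_{level}"]] = v_beh

    _fill("W", S_W)
    _fill("B", S_B)
    theta[IDX["a_B"]] = mbar[1, ATT] - mbar[0, ATT]
    b, g, c = theta[IDX["b_B"]], theta[IDX["g_B"]], theta[IDX["c_B"]]
    m0 = mbar[0]
    theta[IDX["nu_att"]] = m0[ATT]
    theta[IDX["nu_norm"]] = m0[NORM]
    theta[IDX["nu_int"]] = m0[INT] - b * m0[ATT] - g * m0[NORM]
    theta[IDX["nu_beh"]] = m0[BEH] - c * m0[INT]
    if not np.all(np.isfinite(theta)):
        theta[~np.isfinite(theta)] = 0.3
    return theta


@dataclass
class MLFit:
    """Result of a maximum-likelihood fit."""

    theta_hat: np.ndarray | None
    vcov: np.ndarray | None
    neg2loglik: float
    status: str                      # converged | not_converged | failed
    warnings: set[str] = field(default_factory=set)
    message: str = ""
    n_iter: int = 0

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES

    def param(self, name: str) -> float:
        if self.theta_hat is None:
            raise ValueError("no estimates available (fit failed)")
        return float(self.theta_hat[IDX[name]])

    @property
    def params(self) -> PathModelParams:
        if self.theta_hat is None:
            raise ValueError("no estimates available (fit failed)")
        return _theta_to_params(self.theta_hat)


def _numerical_hessian(x: np.ndarray, stats: SufficientStats) -> np.ndarray:
    """Central-difference Hessian with step 1e-5 * (1 + |theta_k|),
    assembled from one batched likelihood evaluation."""
    k = len(x)
    h = 1e-5 * (1.0 + np.abs(x))
    points = [x]
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        points.append(x + ei)
        points.append(x - ei)
    pairs = []
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            pairs.append((i, j))
            points.extend([x + ei + ej, x + ei - ej, x - ei + ej, x - ei - ej])
    f = _batch_neg2ll(np.array(points), stats)
    H = np.zeros((k, k))
    f0 = f[0]
    for i in range(k):
        H[i, i] = (f[1 + 2 * i] - 2.0 * f0 + f[2 + 2 * i]) / (h[i] * h[i])
    base = 1 + 2 * k
    for p, (i, j) in enumerate(pairs):
        fpp, fpm, fmp, fmm = f[base + 4 * p : base + 4 * p + 4]
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _batch_gradient(x: np.ndarray, stats: SufficientStats) -> np.ndarray:
    """Central-difference gradient from one batched evaluation; falls back
    to one-sided differences next to the positive-definite boundary."""
    k = len(x)
    h = 6e-6 * (1.0 + np.abs(x))
    points = np.repeat(x[None, :], 2 * k + 1, axis=0)
    for i in range(k):
        points[1 + 2 * i, i] += h[i]
        points[2 + 2 * i, i] -= h[i]
    f = _batch_neg2ll(points, stats)
    f0 = f[0]
    fp, fm = f[1::2], f[2::2]
    with np.errstate(invalid="ignore"):
        grad = (fp - fm) / (2.0 * h)
        bad = ~np.isfinite(grad)
        if bad.any():
            one_sided = np.where(
                np.isfinite(fp), (fp - f0) / h, (f0 - fm) / h
            )
            grad[bad] = one_sided[bad]
            grad[~np.isfinite(grad)] = 0.0
    return grad


def fit_ml(
    data: pd.DataFrame,
    *,
    maxiter: int = 500,
    ftol: float = 1e-8,
    gtol: float = 1e-6,
    start: np.ndarray | None = None,
) -> MLFit:
    """Fit the two-level path model by quasi-Newton ML.

    All 21 parameters (within/between coefficients, intercepts, variances
    and covariances) are free and unconstrained; standard errors come from
    the numerically differentiated observed information.  Never raises on
    pathological data — failures are reported through ``status`` and
    ``warnings``.
    """
    try:
        stats = sufficient_stats(data)
    except ValueError as exc:
        return MLFit(None, None, np.inf, "failed", {"OTHER"}, message=str(exc))
    if stats.J_arm.min() < 2:
        return MLFit(
            None, None, np.inf, "failed", {"OTHER"},
            message="under-identified between structure: need >= 2 clusters per condition",
        )

    theta0 = moment_start(stats) if start is None else np.asarray(start, dtype=float)
    obj = lambda th: _neg2ll(th, stats)
    jac = lambda th: _batch_gradient(np.asarray(th, dtype=float), stats)
    try:
        res = optimize.minimize(
            obj,
            theta0,
            jac=jac,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol, "maxcor": 25},
        )
    except Exception as exc:  # optimizer blow-up on pathological data
        return MLFit(None, None, np.inf, "failed", {"OTHER"}, message=str(exc))

    warnings: set[str] = set()
    theta_hat = np.asarray(res.x, dtype=float)
    f_hat = float(res.fun)
    if not np.isfinite(f_hat):
        return MLFit(theta_hat, None, f_hat, "failed", {"OTHER"},
                     message="non-finite optimum", n_iter=res.nit)
    if res.nit >= maxiter:
        warnings.add("MAX_ITER")
        status = "not_converged"
    elif not res.success:
        status = "failed"
    else:
        status = "converged"

    # inadmissibility flags at the optimum
    if any(theta_hat[IDX[v]] < 0 for v in _VARIANCE_NAMES):
        warnings.add("NEG_VARIANCE")
    sigma_W, sigma_B, _, _ = _batch_moments(theta_hat[None, :])
    if np.linalg.eigvalsh(sigma_W[0]).min() < 0:
        warnings.add("NPD_WITHIN")
    if np.linalg.eigvalsh(sigma_B[0]).min() < 0:
        warnings.add("NPD_BETWEEN")

    vcov = None
    if status == "converged":
        try:
            H = _numerical_hessian(theta_hat, stats)
            if not np.all(np.isfinite(H)):
                raise np.linalg.LinAlgError("non-finite Hessian")
            # observed information = H/2 (H is the Hessian of -2logL);
            # require it positive definite for usable standard errors
            c = sla.cho_factor((H + H.T) / 4.0, lower=True)
            vcov = sla.cho_solve(c, np.eye(N_PARAMS))
            vcov = (vcov + vcov.T) / 2.0
        except (sla.LinAlgError, np.linalg.LinAlgError, ValueError):
            vcov = None
            warnings.add("SE_FAIL")

    return MLFit(
        theta_hat=theta_hat,
        vcov=vcov,
        neg2loglik=f_hat,
        status=status,
        warnings=warnings,
        message=str(res.message),
        n_iter=int(res.nit),
    )


@dataclass(frozen=True)
class MLInference:
    """Delta-method inference on the indirect effect a_B * b_B * c_B."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool


def ml_inference(fit: MLFit) -> MLInference:
    """Point estimate, delta-method SE, symmetric 95% CI and Wald test.

    With gradient (bc, ac, ab) and V the covariance of (a, b, c)::

        se^2 = b^2c^2 V_aa + a^2c^2 V_bb + a^2b^2 V_cc
             + 2abc^2 V_ab + 2ab^2c V_ac + 2a^2bc V_bc

    Raises ``ValueError`` when no parameter covariance is available
    (SE_FAIL propagates to the caller).
    """
    if fit.theta_hat is None or fit.vcov is None:
        raise ValueError("inference unavailable: fit has no parameter covariance (SE_FAIL)")
    a, b, c = (fit.param(name) for name in _ABC)
    idx = [IDX[name] for name in _ABC]
    V = fit.vcov[np.ix_(idx, idx)]
    grad = np.array([b * c, a * c, a * b])
    var = float(grad @ V @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    est = indirect_effect(a, b, c)
    half = 1.96 * se
    significant = bool(abs(est) > 1.96 * se) if se > 0 else bool(est != 0)
    return MLInference(est, se, est - half, est + half, significant)


@dataclass(frozen=True)
class FitClassification:
    complete: bool
    warning_types: frozenset[str]


def classify_fit(fit: MLFit) -> FitClassification:
    """Classify a fit as complete/incomplete and collect warning types.

    A replication is *complete* when the optimizer converged to a finite
    optimum and the observed information was positive definite (standard
    errors computable) — without usable standard errors the replication
    contributes no interval or test and is counted as incomplete.
    Warning types among complete runs flag inadmissible solutions
    (NEG_VARIANCE, NPD_WITHIN, NPD_BETWEEN); MAX_ITER and OTHER mark
    non-convergence and numerical exceptions.
    """
    complete = (
        fit.status == "converged"
        and np.isfinite(fit.neg2loglik)
        and fit.vcov is not None
    )
    return FitClassification(complete=complete, warning_types=frozenset(fit.warnings))
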