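"""Gibbs-sampler (MCMC) estimation of the two-level path model.

The sampler uses data augmentation: per cluster, the latent between-level
4-vector (attitude_B, norms_B, intention_B, behavior_B) is drawn from its
Gaussian full conditional; given the latent vectors the model splits into
ordinary conjugate regressions at each level.  Priors are the flat defaults
of the study protocol: N(0, 10^10) on every path coefficient and intercept,
IG(-1, 0) on each scalar residual variance (density proportional to 1 on
the variance; the full conditionals stay proper inverse gammas whenever the
residual degrees of freedom allow), and the analogous improper limit of the
inverse Wishart (density proportional to 1) on the two 2x2 attitude-norms
exogenous blocks.

Four chains (by default) run for at least ``min_iter`` iterations and until
the Gelman-Rubin potential scale reduction of every monitored parameter —
all structural coefficients and variances, plus the indirect effect itself
— drops below the threshold, checking every ``psr_check_every`` iterations
up to ``max_iter``.  Point estimate and interval for the indirect effect
a_B*b_B*c_B are the posterior median and the 2.5/97.5 percentiles of the
post-burn-in draws pooled across chains (burn-in = first half of each
chain).

All updates are vectorized over a "lane" axis so that a Monte Carlo batch
of replications can run its chains jointly (``run_mcmc_batch``); the
single-dataset entry point :func:`run_mcmc` is the one-replication case of
the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .ml_estimator import IDX as ML_IDX
from .ml_estimator import SufficientStats, moment_start, sufficient_stats

__all__ = [
    "PriorConfig",
    "MCMCDraws",
    "PosteriorResult",
    "run_mcmc",
    "run_mcmc_batch",
    "psr",
    "summarize_indirect",
]

# sampled parameters, in draw-storage order
PARAM_NAMES = (
    "a_B", "b_W", "b_B", "g_W", "g_B", "c_W", "c_B",
    "nu_att", "nu_norm", "nu_int", "nu_beh",
    "var_att_W", "var_norm_W", "cov_attnorm_W", "var_int_W", "var_beh_W",
    "var_att_B", "var_norm_B", "cov_attnorm_B", "var_int_B", "var_beh_B",
    "indirect",
)
IDX = {name: i for i, name in enumerate(PARAM_NAMES)}
N_STORE = len(PARAM_NAMES)

#: parameters monitored by the PSR convergence criterion
MONITORED = tuple(
    n for n in PARAM_NAMES if not (n.startswith("nu_") or n.startswith("cov_"))
)
_MON_IDX = np.array([IDX[nm] for nm in MONITORED])


@dataclass(frozen=True)
class PriorConfig:
    """Prior configuration for the Gibbs sampler.

    Defaults reproduce the study protocol: ``coef_var=1e10`` (a very flat
    normal on coefficients and intercepts) and ``ig_shape=-1, ig_scale=0``
    (flat on each variance).  ``coef_prior="uniform"`` switches the
    coefficient updates to truncated-normal scalar Gibbs steps on
    ``coef_bounds`` — exposed as a knob only, not part of the evaluated
    protocol.
    """

    coef_mean: float = 0.0
    coef_var: float = 1e10
    ig_shape: float = -1.0
    ig_scale: float = 0.0
    coef_prior: str = "normal"  # "normal" | "uniform"
    coef_bounds: tuple[float, float] = (-10.0, 10.0)


@dataclass
class MCMCDraws:
    """Stored chains: shape (n_chains, n_iter, len(param_names))."""

    chains: np.ndarray
    param_names: tuple[str, ...]
    n_burn: int
    psr_trace: dict[str, float]
    converged: bool
    n_iter: int

    def draws(self, name: str, pooled: bool = True) -> np.ndarray:
        """Post-burn-in draws of one parameter (pooled across chains)."""
        x = self.chains[:, self.n_burn : self.n_iter, IDX[name]]
        return x.ravel() if pooled else x


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior median, 95% percentile credible interval, and the
    interval-exclusion significance decision for the indirect effect."""

    median: float
    ci_low: float
    ci_high: float
    significant: bool
    skewness: float  # (ci_high - median) / (median - ci_low), width asymmetry
    n_draws: int


def psr(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction on the second half of each chain.

    With m chains of post-burn length L, W the mean within-chain variance
    and B = L * var(chain means)::

        PSR = sqrt(((L-1)/L * W + B/L) / W)

    Exact copies give sqrt((L-1)/L) <= 1; chains exploring disjoint regions
    give values far above 1; W = 0 with B > 0 gives +inf (not converged).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("psr needs >= 2 chains with length >= 4")
    return float(_psr_nd(x[None, :, :, None])[0, 0])


def _psr_nd(x: np.ndarray) -> np.ndarray:
    """PSR on the second half, batched: x has shape (R, m, L, K)."""
    x = x[:, :, x.shape[2] // 2 :, :]
    L = x.shape[2]
    W = x.var(axis=2, ddof=1).mean(axis=1)
    B = L * x.mean(axis=2).var(axis=1, ddof=1)
    out = np.full(W.shape, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.sqrt(((L - 1) / L * W + B / L) / W)
    nz = W > 0.0
    out[nz] = val[nz]
    out[(~nz) & (B == 0.0)] = 1.0
    return out


# ---------------------------------------------------------------------------
# full-conditional draws (vectorized over the lane axis)


def _draw_invgamma(rng, shape: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-gamma draw; requires shape > 0 (proper full conditional)."""
    if shape <= 0:
        raise ValueError(
            "improper inverse-gamma full conditional (too few residual df)"
        )
    g = rng.standard_gamma(shape, size=scale.shape)
    return scale / g


def _draw_invwishart2(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Batched 2x2 inverse-Wishart draws via the Bartlett decomposition.

    ``scale`` has shape (L, 2, 2); the draw is inv(Wishart(df, inv(scale))).
    """
    if df <= 1:
        raise ValueError("improper inverse-Wishart full conditional (df <= 1)")
    L_ = scale.shape[0]
    det = scale[:, 0, 0] * scale[:, 1, 1] - scale[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(scale[:, 0, 0] <= 0):
        raise ValueError("degenerate scale matrix in inverse-Wishart step")
    inv00 = scale[:, 1, 1] / det
    inv11 = scale[:, 0, 0] / det
    inv01 = -scale[:, 0, 1] / det
    l11 = np.sqrt(inv00)
    l21 = inv01 / l11
    l22 = np.sqrt(inv11 - l21**2)
    # Bartlett factor: chi draws on the diagonal, one normal below
    a11 = np.sqrt(2.0 * rng.standard_gamma(df / 2.0, size=L_))
    a22 = np.sqrt(2.0 * rng.standard_gamma((df - 1.0) / 2.0, size=L_))
    a21 = rng.standard_normal(L_)
    t11 = l11 * a11
    t21 = l21 * a11 + l22 * a21
    t22 = l22 * a22
    w11 = t11**2
    w21 = t11 * t21
    w22 = t21**2 + t22**2
    dw = w11 * w22 - w21**2
    phi = np.empty_like(scale)
    phi[:, 0, 0] = w22 / dw
    phi[:, 1, 1] = w11 / dw
    phi[:, 0, 1] = phi[:, 1, 0] = -w21 / dw
    return phi


def _draw_coef_block(
    rng,
    prec: np.ndarray,
    rhs: np.ndarray,
    current: np.ndarray,
    priors: PriorConfig,
) -> np.ndarray:
    """Draw coefficient blocks from N(prec^-1 rhs, prec^-1), batched (L,k,k).

    The prior precision contribution must already be inside ``prec``/``rhs``.
    Under the uniform-prior knob the block is updated by sequential scalar
    truncated-normal Gibbs steps instead (still a valid sampler).
    """
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
    if priors.coef_prior == "normal":
        Lc = np.linalg.cholesky(prec)
        z = rng.standard_normal(mean.shape)
        # x = mean + Lc^-T z solves the precision-form sampling identity
        x = np.linalg.solve(np.swapaxes(Lc, -1, -2), z[..., None])[..., 0]
        return mean + x
    lo, hi = priors.coef_bounds
    x = current.copy()
    k = x.shape[-1]
    for i in range(k):
        # conditional of coordinate i given the rest under N(mean, prec^-1)
        pii = prec[..., i, i]
        resid = np.einsum("cj,cj->c", prec[..., i, :], x - mean) - pii * (
            x[..., i] - mean[..., i]
        )
        mu_i = mean[..., i] - resid / pii
        sd_i = 1.0 / np.sqrt(pii)
        a = ndtr((lo - mu_i) / sd_i)
        b = ndtr((hi - mu_i) / sd_i)
        u = rng.uniform(a, b)
        x[..., i] = mu_i + sd_i * ndtri(np.clip(u, 1e-15, 1 - 1e-15))
    return x


# ---------------------------------------------------------------------------
# lane data and state


@dataclass
class _LaneData:
    """Per-lane (replication x chain) sufficient data for the sampler."""

    n: int               # cluster size (shared by all lanes)
    J: int               # clusters per replication
    J1: float            # treated clusters per replication
    ybar: np.ndarray     # (L, J, 4) cluster means
    Syy: np.ndarray      # (L, 4, 4) total cross-product
    T: np.ndarray        # (L, J) treatment indicator as float

    @property
    def M(self) -> int:
        return self.n * self.J

    @property
    def n_lanes(self) -> int:
        return self.ybar.shape[0]

    def subset(self, lanes: np.ndarray) -> "_LaneData":
        return _LaneData(
            self.n, self.J, self.J1,
            self.ybar[lanes], self.Syy[lanes], self.T[lanes],
        )


_STATE_KEYS = (
    "a_B", "b_W", "b_B", "g_W", "g_B", "c_W", "c_B",
    "nu", "phi_W", "phi_B",
    "var_int_W", "var_beh_W", "var_int_B", "var_beh_B",
)


def _subset_state(state: dict, lanes: np.ndarray) -> dict:
    return {k: v[lanes] for k, v in state.items()}


def _prepare_lane_arrays(data: pd.DataFrame):
    """Cluster means, total cross-product and treatment vector of a dataset."""
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
    treat = np.zeros(J, dtype=int)
    np.maximum.at(treat, inv, data["treatment"].to_numpy().astype(int))
    return n, J, ybar, y.T @ y, treat.astype(float)


def _init_state(stats: SufficientStats, n_chains: int, rng) -> dict[str, np.ndarray]:
    """Overdispersed chain starts around the moment estimates.

    Coefficients and intercepts are jittered with twice a crude moment SE
    (2/sqrt(M) within, 2/sqrt(J) between), scaled up with the chain index;
    variances are jittered multiplicatively and floored away from zero.
    """
    theta = moment_start(stats)
    C = n_chains
    M, J = stats.M, stats.J
    factor = 1.0 + np.arange(C)[:, None] / 2.0  # chain-indexed overdispersion
    state: dict[str, np.ndarray] = {}

    def _jit_coef(names, se):
        vals = np.array([theta[ML_IDX[n]] for n in names])
        return vals[None, :] + factor * rng.normal(0.0, 2.0 * se, size=(C, len(names)))

    w_coef = _jit_coef(["b_W", "g_W", "c_W"], 1.0 / np.sqrt(M))
    b_coef = _jit_coef(["a_B", "b_B", "g_B", "c_B"], 1.0 / np.sqrt(J))
    state["nu"] = _jit_coef(["nu_att", "nu_norm", "nu_int", "nu_beh"], 1.0 / np.sqrt(J))
    state["b_W"], state["g_W"], state["c_W"] = (w_coef[:, i].copy() for i in range(3))
    state["a_B"], state["b_B"], state["g_B"], state["c_B"] = (
        b_coef[:, i].copy() for i in range(4)
    )

    def _jit_var(name, df):
        v = max(theta[ML_IDX[name]], 0.05)
        mult = np.exp(factor[:, 0] * rng.normal(0.0, min(0.5, 4.0 / np.sqrt(df)), C))
        return np.maximum(v * mult, 1e-3)

    for name, df in (
        ("var_int_W", M), ("var_beh_W", M), ("var_int_B", J), ("var_beh_B", J),
    ):
        state[name] = _jit_var(name, df)
    for level, df in (("W", M), ("B", J)):
        v1 = _jit_var(f"var_att_{level}", df)
        v2 = _jit_var(f"var_norm_{level}", df)
        cov0 = theta[ML_IDX[f"cov_attnorm_{level}"]]
        cov = np.clip(
            cov0 + factor[:, 0] * rng.normal(0.0, 2.0 / np.sqrt(df), C),
            -0.9 * np.sqrt(v1 * v2),
            0.9 * np.sqrt(v1 * v2),
        )
        phi = np.zeros((C, 2, 2))
        phi[:, 0, 0] = v1
        phi[:, 1, 1] = v2
        phi[:, 0, 1] = phi[:, 1, 0] = cov
        state[f"phi_{level}"] = phi
    return state


def _sigma_from(state, level: str):
    """Level covariance implied by current structural draws, (L, 4, 4)."""
    L_ = state["phi_W"].shape[0]
    b = state[f"b_{level}"]
    g = state[f"g_{level}"]
    c = state[f"c_{level}"]
    A = np.broadcast_to(np.eye(4), (L_, 4, 4)).copy()
    A[:, 2, 0] = b
    A[:, 2, 1] = g
    A[:, 3, 2] = c
    A[:, 3, 0] = c * b
    A[:, 3, 1] = c * g
    Psi = np.zeros((L_, 4, 4))
    Psi[:, :2, :2] = state[f"phi_{level}"]
    Psi[:, 2, 2] = state[f"var_int_{level}"]
    Psi[:, 3, 3] = state[f"var_beh_{level}"]
    return A, A @ Psi @ A.transpose(0, 2, 1)


def _gibbs_iterations(
    data: _LaneData,
    state: dict[str, np.ndarray],
    rng,
    priors: PriorConfig,
    n_iters: int,
    out: np.ndarray,
) -> None:
    """Advance all lanes ``n_iters`` Gibbs sweeps, recording into
    ``out`` of shape (L, n_iters, N_STORE)."""
    n, J, J1 = data.n, data.J, data.J1
    M = data.M
    ybar, Syy, T = data.ybar, data.Syy, data.T
    tau0 = 1.0 / priors.coef_var
    ig_shape_W = priors.ig_shape + M / 2.0
    ig_shape_B = priors.ig_shape + J / 2.0
    iw_df_W = M - 3.0  # flat-prior inverse-Wishart df for the 2x2 blocks
    iw_df_B = J - 3.0
    Lanes = data.n_lanes

    for t in range(n_iters):
        # --- latent between vectors ---
        _, sigma_W = _sigma_from(state, "W")
        A_B, sigma_B = _sigma_from(state, "B")
        nu = state["nu"]
        nu1 = nu.copy()
        nu1[:, 0] += state["a_B"]
        m0 = np.einsum("cij,cj->ci", A_B, nu)
        m1 = np.einsum("cij,cj->ci", A_B, nu1)
        inv_B = np.linalg.inv(sigma_B)
        inv_W = np.linalg.inv(sigma_W)
        post_cov = np.linalg.inv(inv_B + n * inv_W)
        Lc = np.linalg.cholesky(post_cov)
        base = np.where(
            T[:, :, None] > 0,
            np.einsum("cij,cj->ci", inv_B, m1)[:, None, :],
            np.einsum("cij,cj->ci", inv_B, m0)[:, None, :],
        )
        # inv_W and post_cov are symmetric, so x @ S == (S x')'
        mean = (base + n * (ybar @ inv_W)) @ post_cov
        eta = mean + rng.standard_normal((Lanes, J, 4)) @ Lc.transpose(0, 2, 1)

        # --- within model, from the residual scatter ---
        cross = ybar.transpose(0, 2, 1) @ eta
        Sw = (
            Syy
            - n * (cross + cross.transpose(0, 2, 1))
            + n * (eta.transpose(0, 2, 1) @ eta)
        )
        state["phi_W"] = _draw_invwishart2(rng, iw_df_W, Sw[:, :2, :2])
        # intention on (attitude, norms); within components have no intercept
        s2 = state["var_int_W"]
        prec = Sw[:, :2, :2] / s2[:, None, None]
        prec[:, 0, 0] += tau0
        prec[:, 1, 1] += tau0
        bg = _draw_coef_block(
            rng, prec, Sw[:, :2, 2] / s2[:, None],
            np.stack([state["b_W"], state["g_W"]], -1), priors,
        )
        state["b_W"], state["g_W"] = bg[:, 0], bg[:, 1]
        sse = (
            Sw[:, 2, 2]
            - 2.0 * np.einsum("ck,ck->c", bg, Sw[:, :2, 2])
            + np.einsum("ck,ckl,cl->c", bg, Sw[:, :2, :2], bg)
        )
        state["var_int_W"] = _draw_invgamma(
            rng, ig_shape_W, priors.ig_scale + np.maximum(sse, 1e-12) / 2.0
        )
        # behavior on intention
        s2 = state["var_beh_W"]
        prec1 = (Sw[:, 2, 2] / s2 + tau0)[:, None, None]
        cW = _draw_coef_block(
            rng, prec1, (Sw[:, 2, 3] / s2)[:, None], state["c_W"][:, None], priors
        )[:, 0]
        state["c_W"] = cW
        sse = Sw[:, 3, 3] - 2.0 * cW * Sw[:, 2, 3] + cW**2 * Sw[:, 2, 2]
        state["var_beh_W"] = _draw_invgamma(
            rng, ig_shape_W, priors.ig_scale + np.maximum(sse, 1e-12) / 2.0
        )

        # --- between model, on the latent vectors ---
        att, nrm, itn, beh = (eta[:, :, k] for k in range(4))
        # attitude & norms block: residual scatter -> Phi_B, then a GLS draw
        # of (nu_att, a_B, nu_norm) with correlated 2x2 errors
        e1 = att - state["nu"][:, 0:1] - state["a_B"][:, None] * T
        e2 = nrm - state["nu"][:, 1:2]
        SB2 = np.empty((Lanes, 2, 2))
        SB2[:, 0, 0] = np.einsum("cj,cj->c", e1, e1)
        SB2[:, 1, 1] = np.einsum("cj,cj->c", e2, e2)
        SB2[:, 0, 1] = SB2[:, 1, 0] = np.einsum("cj,cj->c", e1, e2)
        phi_B = _draw_invwishart2(rng, iw_df_B, SB2)
        state["phi_B"] = phi_B
        det = phi_B[:, 0, 0] * phi_B[:, 1, 1] - phi_B[:, 0, 1] ** 2
        q11 = phi_B[:, 1, 1] / det
        q22 = phi_B[:, 0, 0] / det
        q12 = -phi_B[:, 0, 1] / det
        sa, sn = att.sum(axis=1), nrm.sum(axis=1)
        sta = np.einsum("cj,cj->c", att, T)
        stn = np.einsum("cj,cj->c", nrm, T)
        prec3 = np.empty((Lanes, 3, 3))
        prec3[:, 0, 0] = J * q11 + tau0
        prec3[:, 0, 1] = prec3[:, 1, 0] = J1 * q11
        prec3[:, 0, 2] = prec3[:, 2, 0] = J * q12
        prec3[:, 1, 1] = J1 * q11 + tau0
        prec3[:, 1, 2] = prec3[:, 2, 1] = J1 * q12
        prec3[:, 2, 2] = J * q22 + tau0
        rhs3 = np.stack(
            [q11 * sa + q12 * sn, q11 * sta + q12 * stn, q12 * sa + q22 * sn], axis=-1
        )
        cur = np.stack([state["nu"][:, 0], state["a_B"], state["nu"][:, 1]], axis=-1)
        b3 = _draw_coef_block(rng, prec3, rhs3, cur, priors)
        state["nu"][:, 0] = b3[:, 0]
        state["a_B"] = b3[:, 1]
        state["nu"][:, 1] = b3[:, 2]
        # intention on (1, attitude, norms)
        XtX = np.empty((Lanes, 3, 3))
        XtX[:, 0, 0] = J
        XtX[:, 0, 1] = XtX[:, 1, 0] = sa
        XtX[:, 0, 2] = XtX[:, 2, 0] = sn
        XtX[:, 1, 1] = np.einsum("cj,cj->c", att, att)
        XtX[:, 1, 2] = XtX[:, 2, 1] = np.einsum("cj,cj->c", att, nrm)
        XtX[:, 2, 2] = np.einsum("cj,cj->c", nrm, nrm)
        Xty = np.stack(
            [
                itn.sum(axis=1),
                np.einsum("cj,cj->c", att, itn),
                np.einsum("cj,cj->c", nrm, itn),
            ],
            axis=-1,
        )
        yty = np.einsum("cj,cj->c", itn, itn)
        s2 = state["var_int_B"]
        prec = XtX / s2[:, None, None]
        prec[:, np.arange(3), np.arange(3)] += tau0
        cur = np.stack([state["nu"][:, 2], state["b_B"], state["g_B"]], -1)
        bi = _draw_coef_block(rng, prec, Xty / s2[:, None], cur, priors)
        state["nu"][:, 2] = bi[:, 0]
        state["b_B"] = bi[:, 1]
        state["g_B"] = bi[:, 2]
        sse = (
            yty
            - 2.0 * np.einsum("ck,ck->c", bi, Xty)
            + np.einsum("ck,ckl,cl->c", bi, XtX, bi)
        )
        state["var_int_B"] = _draw_invgamma(
            rng, ig_shape_B, priors.ig_scale + np.maximum(sse, 1e-12) / 2.0
        )
        # behavior on (1, intention)
        XtX2 = np.empty((Lanes, 2, 2))
        XtX2[:, 0, 0] = J
        XtX2[:, 0, 1] = XtX2[:, 1, 0] = itn.sum(axis=1)
        XtX2[:, 1, 1] = yty
        Xty2 = np.stack([beh.sum(axis=1), np.einsum("cj,cj->c", itn, beh)], axis=-1)
        s2 = state["var_beh_B"]
        prec = XtX2 / s2[:, None, None]
        prec[:, np.arange(2), np.arange(2)] += tau0
        cur = np.stack([state["nu"][:, 3], state["c_B"]], -1)
        bb = _draw_coef_block(rng, prec, Xty2 / s2[:, None], cur, priors)
        state["nu"][:, 3] = bb[:, 0]
        state["c_B"] = bb[:, 1]
        sse = (
            np.einsum("cj,cj->c", beh, beh)
            - 2.0 * np.einsum("ck,ck->c", bb, Xty2)
            + np.einsum("ck,ckl,cl->c", bb, XtX2, bb)
        )
        state["var_beh_B"] = _draw_invgamma(
            rng, ig_shape_B, priors.ig_scale + np.maximum(sse, 1e-12) / 2.0
        )

        # --- record ---
        col = out[:, t, :]
        col[:, IDX["a_B"]] = state["a_B"]
        col[:, IDX["b_W"]] = state["b_W"]
        col[:, IDX["b_B"]] = state["b_B"]
        col[:, IDX["g_W"]] = state["g_W"]
        col[:, IDX["g_B"]] = state["g_B"]
        col[:, IDX["c_W"]] = state["c_W"]
        col[:, IDX["c_B"]] = state["c_B"]
        col[:, IDX["nu_att"] : IDX["nu_beh"] + 1] = state["nu"]
        col[:, IDX["var_att_W"]] = state["phi_W"][:, 0, 0]
        col[:, IDX["var_norm_W"]] = state["phi_W"][:, 1, 1]
        col[:, IDX["cov_attnorm_W"]] = state["phi_W"][:, 0, 1]
        col[:, IDX["var_int_W"]] = state["var_int_W"]
        col[:, IDX["var_beh_W"]] = state["var_beh_W"]
        col[:, IDX["var_att_B"]] = state["phi_B"][:, 0, 0]
        col[:, IDX["var_norm_B"]] = state["phi_B"][:, 1, 1]
        col[:, IDX["cov_attnorm_B"]] = state["phi_B"][:, 0, 1]
        col[:, IDX["var_int_B"]] = state["var_int_B"]
        col[:, IDX["var_beh_B"]] = state["var_beh_B"]
        col[:, IDX["indirect"]] = state["a_B"] * state["b_B"] * state["c_B"]


def _empty_result(n_chains: int) -> MCMCDraws:
    return MCMCDraws(
        chains=np.empty((n_chains, 0, N_STORE)),
        param_names=PARAM_NAMES,
        n_burn=0,
        psr_trace={nm: np.inf for nm in MONITORED},
        converged=False,
        n_iter=0,
    )


def _run_many(
    lane_data: _LaneData,
    states: dict[str, np.ndarray],
    n_reps: int,
    n_chains: int,
    rng,
    priors: PriorConfig,
    min_iter: int,
    psr_threshold: float,
    max_iter: int,
    psr_check_every: int,
) -> list[MCMCDraws]:
    """Shared driver: run R replications x C chains until each replication's
    monitored PSRs clear the threshold (or max_iter)."""
    R, C = n_reps, n_chains
    results: list[MCMCDraws | None] = [None] * R
    draws = np.empty((R, C, min_iter, N_STORE))
    flat = draws.reshape(R * C, min_iter, N_STORE)
    try:
        _gibbs_iterations(lane_data, states, rng, priors, min_iter, flat)
        failed = ~np.all(np.isfinite(flat[:, -1, :]), axis=1).reshape(R, C).all(axis=1)
    except (ValueError, np.linalg.LinAlgError):
        # a degenerate full conditional aborts the whole batch block; mark all
        return [_empty_result(C) for _ in range(R)]

    psr_vals = _psr_nd(draws[:, :, :, _MON_IDX])
    done = (np.all(psr_vals < psr_threshold, axis=1) | failed).copy()
    for r in np.flatnonzero(done):
        if failed[r]:
            results[r] = _empty_result(C)
        else:
            results[r] = MCMCDraws(
                chains=draws[r].copy(), param_names=PARAM_NAMES,
                n_burn=min_iter // 2,
                psr_trace=dict(zip(MONITORED, psr_vals[r].tolist())),
                converged=True, n_iter=min_iter,
            )

    alive = np.flatnonzero(~done)
    if alive.size:
        lanes = (alive[:, None] * C + np.arange(C)[None, :]).ravel()
        sub_data = lane_data.subset(lanes)
        sub_state = _subset_state(states, lanes)
        capacity = min(2 * min_iter, max_iter)
        hist = np.empty((alive.size, C, capacity, N_STORE))
        hist[:, :, :min_iter] = draws[alive]
        t = min_iter
        alive_idx = alive.copy()
        while t < max_iter and alive_idx.size:
            step = min(psr_check_every, max_iter - t)
            if t + step > capacity:  # grow the history buffer geometrically
                capacity = min(max(2 * capacity, t + step), max_iter)
                grown = np.empty((alive_idx.size, C, capacity, N_STORE))
                grown[:, :, :t] = hist[:, :, :t]
                hist = grown
            A = alive_idx.size
            block = np.empty((A, C, step, N_STORE))
            try:
                _gibbs_iterations(
                    sub_data, sub_state, rng, priors, step,
                    block.reshape(A * C, step, N_STORE),
                )
            except (ValueError, np.linalg.LinAlgError):
                for r in alive_idx:
                    results[r] = _empty_result(C)
                alive_idx = np.array([], dtype=int)
                break
            hist[:, :, t : t + step] = block
            t += step
            psr_vals = _psr_nd(hist[:, :, :t, _MON_IDX])
            bad = ~np.all(np.isfinite(hist[:, :, t - 1, :]), axis=(1, 2))
            ok = np.all(psr_vals < psr_threshold, axis=1)
            finished = ok | bad | (t >= max_iter)
            for a in np.flatnonzero(finished):
                r = alive_idx[a]
                if bad[a]:
                    results[r] = _empty_result(C)
                else:
                    results[r] = MCMCDraws(
                        chains=hist[a, :, :t].copy(), param_names=PARAM_NAMES,
                        n_burn=t // 2,
                        psr_trace=dict(zip(MONITORED, psr_vals[a].tolist())),
                        converged=bool(ok[a]), n_iter=t,
                    )
            keep = ~finished
            if not keep.all():
                alive_idx = alive_idx[keep]
                hist = hist[keep]
                keep_lanes = np.repeat(keep, C)
                sub_data = sub_data.subset(keep_lanes)
                sub_state = _subset_state(sub_state, keep_lanes)
    return results  # type: ignore[return-value]


def run_mcmc(
    data: pd.DataFrame,
    priors: PriorConfig | None = None,
    n_chains: int = 4,
    min_iter: int = 5000,
    psr_threshold: float = 1.01,
    max_iter: int = 50000,
    seed: int | None = None,
    psr_check_every: int = 100,
) -> MCMCDraws:
    """Run the data-augmented Gibbs sampler on a balanced trial dataset.

    Identical ``seed`` gives identical draws.  Chains are extended past
    ``min_iter`` in blocks of ``psr_check_every`` until every monitored PSR
    is below ``psr_threshold``; hitting ``max_iter`` first marks the run
    non-converged.  Degenerate data that makes a full conditional improper
    aborts the replication with ``converged=False`` and no draws.
    """
    return run_mcmc_batch(
        [data],
        priors=priors,
        n_chains=n_chains,
        min_iter=min_iter,
        psr_threshold=psr_threshold,
        max_iter=max_iter,
        seed=seed,
        psr_check_every=psr_check_every,
    )[0]


def run_mcmc_batch(
    datasets: list[pd.DataFrame],
    priors: PriorConfig | None = None,
    n_chains: int = 4,
    min_iter: int = 5000,
    psr_threshold: float = 1.01,
    max_iter: int = 50000,
    seed: int | None = None,
    psr_check_every: int = 100,
) -> list[MCMCDraws]:
    """Run the sampler on several same-design datasets jointly.

    All chains of all replications advance together (vectorized over a
    replication x chain lane axis), which amortizes per-iteration overhead
    across a Monte Carlo batch.  All datasets must share cluster size and
    cluster count.  One ``seed`` drives the whole batch; results are
    reproducible for a fixed (datasets, seed, batch composition).
    """
    priors = priors or PriorConfig()
    rng = np.random.default_rng(seed)
    R = len(datasets)
    C = n_chains
    prepped = [_prepare_lane_arrays(d) for d in datasets]
    n, J = prepped[0][0], prepped[0][1]
    if any(p[0] != n or p[1] != J for p in prepped):
        raise ValueError("run_mcmc_batch requires a common design across datasets")
    ybar = np.repeat(np.stack([p[2] for p in prepped]), C, axis=0)
    Syy = np.repeat(np.stack([p[3] for p in prepped]), C, axis=0)
    T = np.repeat(np.stack([p[4] for p in prepped]), C, axis=0)
    J1 = float(prepped[0][4].sum())
    lane_data = _LaneData(n=n, J=J, J1=J1, ybar=ybar, Syy=Syy, T=T)

    per_rep_states = [
        _init_state(sufficient_stats(d), C, rng) for d in datasets
    ]
    states = {
        k: np.concatenate([s[k] for s in per_rep_states], axis=0)
        for k in per_rep_states[0]
    }
    return _run_many(
        lane_data, states, R, C, rng, priors,
        min_iter, psr_threshold, max_iter, psr_check_every,
    )


def summarize_indirect(draws: MCMCDraws) -> PosteriorResult:
    """Posterior median, 95% percentile interval and interval-exclusion
    significance for the indirect effect, pooled across chains."""
    x = draws.draws("indirect", pooled=True)
    if x.size == 0:
        raise ValueError("no draws available (replication aborted)")
    med = float(np.median(x))
    lo, hi = (float(q) for q in np.percentile(x, [2.5, 97.5]))
    significant = bool(lo > 0.0 or hi < 0.0)
    upper, lower = hi - med, med - lo
    skew = upper / lower if lower > 0 else np.inf if upper > 0 else 1.0
    return PosteriorResult(
        median=med, ci_low=lo, ci_high=hi,
        significant=significant, skewness=float(skew), n_draws=int(x.size),
    )
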