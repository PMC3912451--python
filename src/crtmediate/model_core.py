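"""Two-level path model for mediation in cluster randomized trials.

The model is a 2-1-1-1 mediation chain: a dichotomous treatment assigned at
the cluster level affects a behavioral outcome only indirectly, through the
chain treatment -> attitude -> intention -> behavior (the planned-behavior
structure, with norms as a correlated second predictor of intention).
Attitude, norms, intention and behavior are individual-level Gaussian
variables decomposed into orthogonal, additive between-cluster and
within-cluster components::

    Y_ij = Y_Bj + Y_Wij,      Sigma_T = Sigma_B + Sigma_W

Each level carries its own structural model.  Treatment is a cluster-level
variable and enters only the between-level mean structure; the indirect
(mediation) effect is the between-level product a * b * c along the chain.

Variable order is fixed everywhere as (attitude, norms, intention, behavior).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "VARIABLES",
    "ATT",
    "NORM",
    "INT",
    "BEH",
    "PathModelParams",
    "ImpliedMoments",
    "implied_moments",
    "indirect_effect",
    "icc",
    "population_defaults",
]

#: canonical variable order, used in every matrix and file in the package
VARIABLES = ("attitude", "norms", "intention", "behavior")
ATT, NORM, INT, BEH = range(4)


@dataclass(frozen=True)
class PathModelParams:
    """All structural coefficients and (co)variances at both levels.

    Defaults are the population values of the simulation study: every
    structural path is the medium effect size 0.5, attitude residual
    variances are 2 (within) and 1 (between), intention and behavior
    residual variances are 1 (within) and 0.5 (between), so the residual
    intraclass correlation of each endogenous variable is 0.33.  Norms
    mirrors attitude (variance 2 within, 1 between) and correlates 0.3
    with attitude at each level.
    """

    a_B: float = 0.5  # treatment -> attitude, between level only
    b_W: float = 0.5  # attitude -> intention
    b_B: float = 0.5
    g_W: float = 0.5  # norms -> intention
    g_B: float = 0.5
    c_W: float = 0.5  # intention -> behavior
    c_B: float = 0.5
    var_att_W: float = 2.0
    var_att_B: float = 1.0
    var_norm_W: float = 2.0
    var_norm_B: float = 1.0
    cov_attnorm_W: float = 0.6  # correlation 0.3 at each level
    cov_attnorm_B: float = 0.3
    var_int_W: float = 1.0
    var_int_B: float = 0.5
    var_beh_W: float = 1.0
    var_beh_B: float = 0.5

    def validate(self) -> None:
        """Raise ``ValueError`` if the parameters cannot generate data.

        Admissibility requires strictly positive variances and attitude-norms
        covariances within the Cauchy-Schwarz bound at each level.  (The ML
        estimator may legitimately *visit* inadmissible values; this check
        guards data generation only.)
        """
        for level in ("W", "B"):
            for var in ("att", "norm", "int", "beh"):
                v = getattr(self, f"var_{var}_{level}")
                if not v > 0:
                    raise ValueError(f"var_{var}_{level} must be > 0, got {v}")
            cov = getattr(self, f"cov_attnorm_{level}")
            bound = np.sqrt(
                getattr(self, f"var_att_{level}") * getattr(self, f"var_norm_{level}")
            )
            if abs(cov) > bound:
                raise ValueError(
                    f"cov_attnorm_{level}={cov} violates |cov| <= sqrt(var*var)={bound:.4g}"
                )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "PathModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def with_updates(self, **kwargs: float) -> "PathModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ImpliedMoments:
    """Model-implied first and second moments.

    ``mu0`` is the mean vector under control (all zeros by construction),
    ``delta`` the reduced-form treatment effect on each observed variable,
    ``sigma_W``/``sigma_B`` the within- and between-cluster covariance
    matrices (the treatment effect lives in ``delta``, not in ``sigma_B``).
    """

    mu0: np.ndarray
    delta: np.ndarray
    sigma_W: np.ndarray
    sigma_B: np.ndarray

    @property
    def sigma_total(self) -> np.ndarray:
        """Total covariance Sigma_T = Sigma_B + Sigma_W (additivity)."""
        return self.sigma_B + self.sigma_W


def _structural_matrices(params: PathModelParams, level: str):
    """Return (B, Psi) for one level; B is the 4x4 coefficient matrix
    (row = dependent variable), Psi the exogenous/residual covariance."""
    b = getattr(params, f"b_{level}")
    g = getattr(params, f"g_{level}")
    c = getattr(params, f"c_{level}")
    B = np.zeros((4, 4))
    B[INT, ATT] = b
    B[INT, NORM] = g
    B[BEH, INT] = c
    Psi = np.zeros((4, 4))
    Psi[ATT, ATT] = getattr(params, f"var_att_{level}")
    Psi[NORM, NORM] = getattr(params, f"var_norm_{level}")
    Psi[ATT, NORM] = Psi[NORM, ATT] = getattr(params, f"cov_attnorm_{level}")
    Psi[INT, INT] = getattr(params, f"var_int_{level}")
    Psi[BEH, BEH] = getattr(params, f"var_beh_{level}")
    return B, Psi


def _reduced_form(B: np.ndarray) -> np.ndarray:
    """(I - B)^-1, with an explicit error for cyclic specifications."""
    eye_minus = np.eye(4) - B
    det = np.linalg.det(eye_minus)
    if abs(det) < 1e-12:
        raise ValueError(
            "singular (I - B): the structural coefficient matrix specifies a cyclic path"
        )
    return np.linalg.inv(eye_minus)


def implied_moments(params: PathModelParams) -> ImpliedMoments:
    """Compute the moment structure implied by the path model.

    Per level L, with reduced form A_L = (I - B_L)^-1::

        Sigma_L = A_L Psi_L A_L'
        delta   = A_B (a_B, 0, 0, 0)'

    so the last entry of ``delta`` is exactly a_B * b_B * c_B, the indirect
    effect of treatment on behavior.
    """
    B_W, Psi_W = _structural_matrices(params, "W")
    B_B, Psi_B = _structural_matrices(params, "B")
    A_W = _reduced_form(B_W)
    A_B = _reduced_form(B_B)
    sigma_W = A_W @ Psi_W @ A_W.T
    sigma_B = A_B @ Psi_B @ A_B.T
    delta = A_B @ np.array([params.a_B, 0.0, 0.0, 0.0])
    return ImpliedMoments(
        mu0=np.zeros(4), delta=delta, sigma_W=sigma_W, sigma_B=sigma_B
    )


def indirect_effect(a: float, b: float, c: float) -> float:
    """Product-of-coefficients indirect effect a * b * c.

    The between-level treatment -> attitude -> intention -> behavior chain
    product; 0.5 * 0.5 * 0.5 = 0.125 at the population values.
    """
    return a * b * c


def icc(var_between: float, var_within: float) -> float:
    """Intraclass correlation var_B / (var_B + var_W).

    Proportion of (residual) variance located at the cluster level; the
    study populations all use residual ICC 1/3 (printed as 0.33).
    """
    if var_between < 0 or var_within < 0:
        raise ValueError("variance components must be non-negative")
    total = var_between + var_within
    if total == 0:
        raise ValueError("icc undefined when both variance components are zero")
    return var_between / total


def population_defaults() -> PathModelParams:
    """The population parameter values of the simulation study."""
    return PathModelParams()
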