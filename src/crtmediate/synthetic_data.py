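"""Balanced cluster-randomized trial data generator.

Emulates the data-generating model of the simulation study: a dichotomous
cluster-level treatment, and four individual-level Gaussian variables built
as the sum of a between-cluster component (drawn per cluster from the
between-level structural model, with the treatment effect on attitude) and a
within-cluster component (drawn per individual from the within-level
structural model).

Reproducibility protocol: one master seed per dataset; the seed is expanded
into one substream per cluster (plus one for the treatment assignment), so
identical seeds give bit-identical datasets regardless of how the cluster
loop is executed.  Draw order within a cluster is fixed: between exogenous
pair, between intention residual, between behavior residual, then the
within exogenous pairs and residual vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import PathModelParams, VARIABLES, population_defaults

__all__ = [
    "COLUMNS",
    "TrialDesign",
    "generate_trial",
    "write_trial_csv",
    "read_trial_csv",
]

#: CSV / DataFrame column order for trial datasets
COLUMNS = ("cluster", "treatment") + VARIABLES


@dataclass(frozen=True)
class TrialDesign:
    """A balanced two-arm cluster-randomized design.

    ``clusters_per_condition`` clusters of ``cluster_size`` members are
    assigned to each arm (study values: 5/10/25/50 clusters per condition,
    sizes 5 or 10), so the total number of clusters is exactly twice
    ``clusters_per_condition`` and exactly half are treated.
    """

    clusters_per_condition: int
    cluster_size: int
    params: PathModelParams = field(default_factory=population_defaults)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.clusters_per_condition < 2:
            raise ValueError("clusters_per_condition must be >= 2")
        if self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")

    @property
    def n_clusters(self) -> int:
        return 2 * self.clusters_per_condition

    @property
    def n_rows(self) -> int:
        return self.n_clusters * self.cluster_size


def _chol2(v1: float, v2: float, cov: float) -> np.ndarray:
    """Cholesky factor of a 2x2 covariance matrix."""
    l11 = np.sqrt(v1)
    l21 = cov / l11
    l22 = np.sqrt(max(v2 - l21 * l21, 0.0))
    return np.array([[l11, 0.0], [l21, l22]])


def generate_trial(design: TrialDesign, seed: int | None = None) -> pd.DataFrame:
    """Generate one balanced trial dataset as a DataFrame.

    Columns are ``cluster, treatment, attitude, norms, intention, behavior``;
    every cluster has exactly ``cluster_size`` rows and treatment is constant
    within cluster.  ``seed`` overrides ``design.seed`` when given.
    """
    p = design.params
    p.validate()
    if seed is None:
        seed = design.seed
    n = design.cluster_size
    J = design.n_clusters

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(J + 1)

    # deterministic balance: shuffle cluster ids, treat the first half
    assign_rng = np.random.default_rng(children[0])
    perm = assign_rng.permutation(J)
    treated = np.zeros(J, dtype=int)
    treated[perm[: design.clusters_per_condition]] = 1

    L_B = _chol2(p.var_att_B, p.var_norm_B, p.cov_attnorm_B)
    L_W = _chol2(p.var_att_W, p.var_norm_W, p.cov_attnorm_W)
    sd_int_B, sd_beh_B = np.sqrt(p.var_int_B), np.sqrt(p.var_beh_B)
    sd_int_W, sd_beh_W = np.sqrt(p.var_int_W), np.sqrt(p.var_beh_W)

    blocks = np.empty((J, n, 4))
    for j in range(J):
        rng = np.random.default_rng(children[j + 1])
        t = treated[j]
        # between components: structural equations in causal order
        eps_att, dev_norm = L_B @ rng.standard_normal(2)
        att_B = p.a_B * t + eps_att
        norm_B = dev_norm
        int_B = p.b_B * att_B + p.g_B * norm_B + sd_int_B * rng.standard_normal()
        beh_B = p.c_B * int_B + sd_beh_B * rng.standard_normal()
        # within components, one row per member
        exog = rng.standard_normal((n, 2)) @ L_W.T
        att_W, norm_W = exog[:, 0], exog[:, 1]
        int_W = p.b_W * att_W + p.g_W * norm_W + sd_int_W * rng.standard_normal(n)
        beh_W = p.c_W * int_W + sd_beh_W * rng.standard_normal(n)
        blocks[j, :, 0] = att_B + att_W
        blocks[j, :, 1] = norm_B + norm_W
        blocks[j, :, 2] = int_B + int_W
        blocks[j, :, 3] = beh_B + beh_W

    df = pd.DataFrame(blocks.reshape(J * n, 4), columns=list(VARIABLES))
    df.insert(0, "treatment", np.repeat(treated, n))
    df.insert(0, "cluster", np.repeat(np.arange(J), n))
    return df


def write_trial_csv(df: pd.DataFrame, path) -> None:
    """Write a trial dataset to CSV (full float precision, UTF-8)."""
    df.to_csv(path, index=False, columns=list(COLUMNS))


def read_trial_csv(path) -> pd.DataFrame:
    """Read a trial dataset written by :func:`write_trial_csv`."""
    df = pd.read_csv(path)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    df["cluster"] = df["cluster"].astype(int)
    df["treatment"] = df["treatment"].astype(int)
    return df[list(COLUMNS)]
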