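"""Monte Carlo harness: populations, per-replication records, summary tables.

The simulation study crosses 5/10/25/50 clusters per treatment condition
with cluster sizes 5/10 into eight populations, analyzed by full ML and by
the Gibbs sampler.  Per population and estimator the harness reports the
mean and SD of the indirect-effect point estimates over complete
replications, the relative bias against the population value 0.125, the
coverage of the nominal 95% interval, the proportion of significant
results, and convergence/warning tallies.

Reproducibility: every replication r gets its own seed pair (data seed,
estimator seed) spawned from the master seed by replication index, so a
condition's per-replication records do not depend on execution order.
Bayesian replications run through :func:`crtmediate.bayes_estimator.run_mcmc_batch`
in fixed-size batches for throughput.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes_estimator import PriorConfig, run_mcmc_batch, summarize_indirect
from .ml_estimator import classify_fit, fit_ml, ml_inference
from .model_core import PathModelParams, indirect_effect, population_defaults
from .synthetic_data import TrialDesign, generate_trial

__all__ = [
    "POPULATIONS",
    "ConditionResult",
    "population_design",
    "run_condition",
    "aggregate_records",
    "table1",
    "table2",
    "load_config",
]

#: population id -> (clusters per condition, cluster size)
POPULATIONS = {
    1: (50, 5),
    2: (50, 10),
    3: (25, 5),
    4: (25, 10),
    5: (10, 5),
    6: (10, 10),
    7: (5, 5),
    8: (5, 10),
}

_ML_WARNING_TYPES = ("NEG_VARIANCE", "NPD_WITHIN", "NPD_BETWEEN", "SE_FAIL", "MAX_ITER", "OTHER")


def population_design(
    pop_id: int,
    params: PathModelParams | None = None,
    seed: int | None = None,
) -> TrialDesign:
    """TrialDesign for one of the eight study populations."""
    if pop_id not in POPULATIONS:
        raise ValueError(f"population id must be 1..8, got {pop_id}")
    J, n = POPULATIONS[pop_id]
    return TrialDesign(J, n, params=params or population_defaults(), seed=seed)


@dataclass
class ConditionResult:
    """Monte Carlo summary of one population x estimator cell."""

    population_id: int | None
    estimator: str                      # "ml" | "bayes"
    n_requested: int
    n_complete: int
    mean_estimate: float
    sd_estimate: float
    relative_bias_pct: float
    coverage_pct: float
    significance_pct: float
    warning_tally: dict[str, int] = field(default_factory=dict)
    true_effect: float = 0.125

    def to_dict(self) -> dict:
        d = {
            "population_id": self.population_id,
            "estimator": self.estimator,
            "n_requested": self.n_requested,
            "n_complete": self.n_complete,
            "mean_estimate": self.mean_estimate,
            "sd_estimate": self.sd_estimate,
            "relative_bias_pct": self.relative_bias_pct,
            "coverage_pct": self.coverage_pct,
            "significance_pct": self.significance_pct,
            "true_effect": self.true_effect,
        }
        d.update({f"warn_{k}": v for k, v in self.warning_tally.items()})
        return d


def aggregate_records(
    records: pd.DataFrame,
    estimator: str,
    true_effect: float = 0.125,
    population_id: int | None = None,
) -> ConditionResult:
    """Summarize per-replication records into a :class:`ConditionResult`.

    Moment, coverage and significance summaries run over *complete*
    replications only; incomplete replications are counted.  The relative
    bias is 100 * (mean - true) / true, computed from the reported mean so
    the two are exactly consistent.
    """
    n_req = len(records)
    complete = records[records["complete"]]
    n_comp = len(complete)
    if n_comp:
        mean_est = float(complete["estimate"].mean())
        sd_est = float(complete["estimate"].std(ddof=1)) if n_comp > 1 else np.nan
        cover = float(
            100.0
            * (
                (complete["ci_low"] <= true_effect)
                & (true_effect <= complete["ci_high"])
            ).mean()
        )
        sig = float(100.0 * complete["significant"].mean())
        rel_bias = 100.0 * (mean_est - true_effect) / true_effect
    else:
        mean_est = sd_est = cover = sig = rel_bias = np.nan
    tally: dict[str, int] = {}
    if estimator == "ml":
        warn_str = records["warnings"].fillna("")
        for w in _ML_WARNING_TYPES:
            count = int(warn_str.str.contains(w, regex=False).sum())
            if count:
                tally[w] = count
        # completed replications with an inadmissible solution (Heywood case
        # or non-positive-definite level covariance)
        inadmissible = complete["warnings"].fillna("").str.contains(
            "NEG_VARIANCE|NPD_WITHIN|NPD_BETWEEN", regex=True
        )
        tally["INADMISSIBLE_COMPLETE"] = int(inadmissible.sum())
        tally["INCOMPLETE"] = n_req - n_comp
    else:
        tally["NON_CONVERGED"] = n_req - n_comp
    return ConditionResult(
        population_id=population_id,
        estimator=estimator,
        n_requested=n_req,
        n_complete=n_comp,
        mean_estimate=mean_est,
        sd_estimate=sd_est,
        relative_bias_pct=float(rel_bias) if n_comp else np.nan,
        coverage_pct=cover,
        significance_pct=sig,
        warning_tally=tally,
        true_effect=true_effect,
    )


def _rep_seeds(master_seed: int | None, n_reps: int) -> list[tuple[int, int]]:
    """Per-replication (data, estimator) seed pairs below 2^31."""
    ss = np.random.SeedSequence(master_seed)
    pairs = []
    for child in ss.spawn(n_reps):
        a, b = child.generate_state(2)
        pairs.append((int(a % 2**31), int(b % 2**31)))
    return pairs


def run_condition(
    design: TrialDesign,
    estimator: str,
    n_reps: int,
    master_seed: int | None = None,
    *,
    population_id: int | None = None,
    priors: PriorConfig | None = None,
    mcmc_options: dict | None = None,
    ml_options: dict | None = None,
    bayes_batch_size: int = 50,
    progress: bool = False,
) -> tuple[ConditionResult, pd.DataFrame]:
    """Run one population x estimator Monte Carlo cell.

    Returns the aggregated :class:`ConditionResult` and the per-replication
    record table (columns ``rep, estimator, estimate, se, ci_low, ci_high,
    significant, status, warnings, complete``).  Per-replication failures
    are recorded, never raised.
    """
    if estimator not in ("ml", "bayes"):
        raise ValueError("estimator must be 'ml' or 'bayes'")
    true = indirect_effect(design.params.a_B, design.params.b_B, design.params.c_B)
    seeds = _rep_seeds(master_seed, n_reps)
    rows: list[dict] = []

    if estimator == "ml":
        for r, (ds, _) in enumerate(seeds):
            data = generate_trial(design, seed=ds)
            fit = fit_ml(data, **(ml_options or {}))
            cls = classify_fit(fit)
            row = {
                "rep": r, "estimator": "ml",
                "estimate": np.nan, "se": np.nan,
                "ci_low": np.nan, "ci_high": np.nan,
                "significant": False, "status": fit.status,
                "warnings": ";".join(sorted(fit.warnings)),
                "complete": cls.complete,
            }
            if cls.complete:
                inf = ml_inference(fit)
                row.update(
                    estimate=inf.estimate, se=inf.se,
                    ci_low=inf.ci_low, ci_high=inf.ci_high,
                    significant=inf.significant,
                )
            rows.append(row)
            if progress and (r + 1) % 100 == 0:
                print(f"  ml rep {r + 1}/{n_reps}")
    else:
        opts = dict(mcmc_options or {})
        for lo in range(0, n_reps, bayes_batch_size):
            chunk = list(range(lo, min(lo + bayes_batch_size, n_reps)))
            datasets = [generate_trial(design, seed=seeds[r][0]) for r in chunk]
            batch_seed = seeds[chunk[0]][1]
            draws_list = run_mcmc_batch(datasets, priors=priors, seed=batch_seed, **opts)
            for r, draws in zip(chunk, draws_list):
                row = {
                    "rep": r, "estimator": "bayes",
                    "estimate": np.nan, "se": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan,
                    "significant": False,
                    "status": "converged" if draws.converged else "not_converged",
                    "warnings": "",
                    "complete": draws.converged,
                }
                if draws.converged:
                    post = summarize_indirect(draws)
                    x = draws.draws("indirect")
                    row.update(
                        estimate=post.median,
                        se=float(x.std(ddof=1)),  # posterior SD, for reference
                        ci_low=post.ci_low, ci_high=post.ci_high,
                        significant=post.significant,
                    )
                rows.append(row)
            if progress:
                print(f"  bayes rep {min(lo + bayes_batch_size, n_reps)}/{n_reps}")

    records = pd.DataFrame(rows)
    result = aggregate_records(
        records, estimator, true_effect=true, population_id=population_id
    )
    return result, records


# ---------------------------------------------------------------------------
# tables


_T1_OUTCOMES = ("mean_sd", "bias", "coverage", "significance")


def table1(results: list[ConditionResult]) -> pd.DataFrame:
    """Bias / coverage / power grid: estimators x outcomes as rows,
    populations as columns; missing cells rendered as NA."""
    pops = sorted({r.population_id for r in results if r.population_id is not None})
    index = pd.MultiIndex.from_product(
        [["ml", "bayes"], list(_T1_OUTCOMES)], names=["estimator", "outcome"]
    )
    cols = [f"pop{p}" for p in pops]
    tab = pd.DataFrame("NA", index=index, columns=cols)
    for r in results:
        if r.population_id is None:
            continue
        col = f"pop{r.population_id}"
        if r.n_complete:
            tab.loc[(r.estimator, "mean_sd"), col] = (
                f"{r.mean_estimate:.4f} ({r.sd_estimate:.4f})"
            )
            tab.loc[(r.estimator, "bias"), col] = f"{r.relative_bias_pct:.2f}"
            tab.loc[(r.estimator, "coverage"), col] = f"{r.coverage_pct:.1f}"
            tab.loc[(r.estimator, "significance"), col] = f"{r.significance_pct:.1f}"
    return tab


def table2(results: list[ConditionResult]) -> pd.DataFrame:
    """Convergence summary for the ML estimator: requested, incomplete,
    complete and inadmissible-solution warning counts per population."""
    rows = []
    for r in sorted(
        (x for x in results if x.estimator == "ml" and x.population_id is not None),
        key=lambda x: x.population_id,
    ):
        n_inc = r.n_requested - r.n_complete
        n_warn = r.warning_tally.get("INADMISSIBLE_COMPLETE", 0)
        rows.append(
            {
                "population": r.population_id,
                "requested": r.n_requested,
                "n_incomplete": n_inc,
                "pct_incomplete": 100.0 * n_inc / r.n_requested if r.n_requested else np.nan,
                "complete": r.n_complete,
                "warnings": n_warn,
                "pct_warnings": 100.0 * n_warn / r.n_complete if r.n_complete else np.nan,
                **{f"warn_{k}": v for k, v in sorted(r.warning_tally.items())},
            }
        )
    return pd.DataFrame(rows)


def load_config(path) -> dict:
    """Read a YAML/JSON config with optional ``params``, ``priors`` and
    ``mcmc`` sections; returns dataclass-ready objects."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    out: dict = {}
    if "params" in cfg:
        out["params"] = PathModelParams.from_dict(cfg["params"])
    if "priors" in cfg:
        out["priors"] = PriorConfig(**cfg["priors"])
    if "mcmc" in cfg:
        out["mcmc_options"] = dict(cfg["mcmc"])
    if "ml" in cfg:
        out["ml_options"] = dict(cfg["ml"])
    return out
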