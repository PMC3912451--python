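# Methods

## Model

Individuals i are nested in clusters j; treatment T_j ∈ {0, 1} is assigned
to whole clusters, exactly half per arm. The observed 4-vector
(attitude, norms, intention, behavior) — this variable order is fixed
everywhere in the package — decomposes additively:

    Y_ij = Y_Bj + Y_Wij,   Y_Bj ⊥ Y_Wij,   Σ_T = Σ_B + Σ_W.

Each level carries a recursive path model. With B_L the strictly
lower-triangular coefficient matrix of level L (attitude → intention,
norms → intention, intention → behavior) and Ψ_L the block-diagonal
exogenous/residual covariance (a 2×2 attitude–norms block plus two
residual variances), the implied covariance is the reduced form

    Σ_L = (I − B_L)⁻¹ Ψ_L (I − B_L)⁻ᵀ .

Treatment enters only the between-level mean structure: the reduced-form
effect on the four observed means is δ = (I − B_B)⁻¹ (a, 0, 0, 0)ᵀ, whose
last entry is exactly the indirect effect a·b·c. Under control all means
are zero.

Population values (generator defaults): every path coefficient 0.5;
attitude residual variance 2 within / 1 between; intention and behavior
residual variances 1 within / 0.5 between (residual ICC = 1/3 for all
three endogenous variables); norms variance 2 within / 1 between with
attitude–norms correlation 0.3 at each level. The norms block is not
printed numerically in the source material; those three choices (variance
mirror of attitude, correlation 0.3, norms → intention = 0.5) are this
package's fixed convention, exposed in `PathModelParams` for sensitivity
work. Because Ψ_B = Ψ_W/2 entrywise with equal coefficients, every
variable's *total* ICC is also exactly 1/3 — a convenient generator
diagnostic used by the tests.

## Data generation

Per cluster: draw the between exogenous pair (attitude residual, norms)
from its 2×2 Gaussian block, add a·T to attitude, then intention and
behavior by the between structural equations; per member: the analogous
within draws; return the sums. One master seed per dataset is expanded
into one substream per cluster (plus one for the shuffled treatment
assignment), so datasets are bit-reproducible and independent of the
cluster loop order. Designs are always balanced; unbalanced sizes,
missingness and extra covariates are out of scope.

## Maximum likelihood

For a balanced cluster of size n the joint covariance
I_n⊗Σ_W + J_n⊗Σ_B factorizes, giving the −2 log likelihood

    Σ_j [ (n−1) log|Σ_W| + tr(Σ_W⁻¹ S_j) + log|Σ_n| + n (ȳ_j − μ_j)ᵀ Σ_n⁻¹ (ȳ_j − μ_j) ] + 4Nn log 2π,

with Σ_n = Σ_W + nΣ_B, S_j the within-cluster scatter and μ_j the arm
mean. The implementation reduces the data once to sufficient statistics
(pooled within scatter; per-arm sums and cross-products of cluster means),
so one evaluation costs a handful of 4×4 operations; gradients and the
observed-information Hessian are central finite differences evaluated in
one vectorized batch. Equality with the dense 4n-dimensional Gaussian
density (2π constant included) is tested to 1e−8.

All 21 parameters (8 within, 13 between including four intercepts/means)
are free and *unconstrained* — no log transform on variances — precisely
so that negative variance estimates and non-positive-definite level
covariances can occur and be tallied, mirroring the inadmissible-solution
phenomenon under study. Outside the positive-definite region the
likelihood returns +inf (optimizer-safe). Optimization is L-BFGS-B from
deterministic moment-based starts (pooled-within regressions; cluster-mean
moments with the Σ_W/n correction, variances floored at 0.05), relative
function tolerance 1e−8, at most 500 iterations.

Inference on a·b·c uses the multivariate delta method on the (a, b, c)
block of 2H⁻¹ (H the Hessian of −2 log L), a symmetric ±1.96·se interval,
and the Wald z at the two-sided 5% level.

Completion rule: a replication is *complete* when the optimizer converged
to a finite optimum **and** the observed information is positive definite
(standard errors exist). A converged fit without usable standard errors
contributes no interval or test, so it is counted as incomplete
(`SE_FAIL`); negative variances / non-PD level covariances among complete
fits are counted as inadmissible-solution warnings. This is a documented
analogue of the closed-source original protocol, whose exact rules are not
public; the package reproduces the *pattern* (breakdown below ~25 clusters
per condition), not cell-exact counts.

## Bayesian estimation

Gibbs sampler with data augmentation. Given parameters, each cluster's
latent between 4-vector η_j has Gaussian full conditional with precision
Σ_B⁻¹ + nΣ_W⁻¹ (the cluster mean is sufficient). Given the η_j, the model
splits into conjugate pieces: the 2×2 attitude–norms blocks are
inverse-Wishart (flat prior, density ∝ 1, posterior df = #obs − 3);
regression coefficient blocks are Gaussian under the N(0, 10¹⁰) prior
(the between attitude/norms equations form a two-equation GLS block with
correlated errors); scalar residual variances are inverse-gamma under
IG(−1, 0), i.e. density ∝ 1 on the variance, proper whenever the residual
degrees of freedom exceed two. Within-level cross-products are computed
from the residual scatter matrix, so one sweep is O(J) after a one-time
O(Nn) reduction.

Protocol: four chains, at least 5000 iterations, Gelman–Rubin PSR
(standard form, computed on the second half of each chain) below 1.01 for
all monitored parameters — every structural coefficient and variance plus
the indirect effect itself — checked every 100 iterations up to a 50 000
cap, after which the replication is recorded non-converged and excluded
from (but counted against) the summaries. Chains start from moment
estimates jittered with chain-indexed overdispersed noise (≈2× a crude
moment SE; variances jittered multiplicatively and floored), as PSR
validity requires. Point estimate = posterior median of the pooled
post-burn-in a·b·c draws (burn-in = first half); interval = 2.5/97.5
percentiles; "significant" = interval excludes zero. Posterior predictive
p-values are deliberately not implemented; interval exclusion is the
decision rule.

A `PriorConfig` knob can replace the normal coefficient prior with a
uniform on a bounded interval (sequential truncated-normal scalar Gibbs
steps); it exists for sensitivity exploration only and is not part of the
evaluated protocol.

Performance: all full conditionals are vectorized over a
replication × chain "lane" axis, so a Monte Carlo batch (default 50
replications) advances all its chains together — about 0.5 s per
replication for 50 clusters of 5 per condition. Consequence: the MCMC
random stream is shared across a batch (one stream derived from the
master seed). Results are exactly reproducible for a fixed master seed
and batch size, but individual replications are not re-runnable in
isolation from the batch; dataset generation keeps strict per-replication
substreams.

## Monte Carlo harness

Eight populations: (clusters per condition, size) =
(50,5), (50,10), (25,5), (25,10), (10,5), (10,10), (5,5), (5,10).
Per population × estimator cell the harness reports, over complete
replications: mean and SD of the point estimates, relative bias
100·(mean − 0.125)/0.125 (computed from the reported mean, so the two are
exactly consistent), 95% interval coverage of 0.125, the significance
rate, and the incompleteness/warning tallies. Summaries over
complete-only replications is this package's documented rule.

Problem sizes (this package's choices for desk-scale runs): the
acceptance script uses 1500/1200 ML and 600/320 Bayesian replications for
populations 1–2 (≈10–15 min on one CPU); the test suite re-runs the same
cells at 1000/500 ML and 300/300 Bayes, plus 8-population pattern grids
at 150 ML / 48 Bayes replications per population (the grid caps MCMC
chains at 20 000 iterations). Full 5000-replication reproduction is a
`--reps` flag away but is a cluster-afternoon, not a desk run.

## Numerical and statistical checks

- Likelihood oracle: balanced factorization ≡ dense Gaussian, ≤1e−8.
- Moment oracle: generator's pooled-within covariance over 10⁶
  individuals matches Σ_W entrywise within 3 MC SEs; cluster-mean
  covariance matches Σ_B + Σ_W/n.
- Conjugate oracles: the coefficient and variance full-conditional
  samplers reproduce the closed-form flat-prior posteriors
  N(β̂_OLS, σ²(XᵀX)⁻¹), IG(n/2 − 1, SSE/2), and the inverse-Wishart
  posterior mean. (The degenerate single-level sub-case is covered at
  this block level; the two-level sampler itself requires cluster size
  ≥ 2.) On a large dataset posterior medians track the ML estimates.
- PSR sanity: copied chains ≤ 1; independent well-mixed chains within
  0.01 of 1; disjoint chains far above 1.1.
- Pattern properties at reduced scale, with 2-MC-SE slack: power
  non-decreasing in the number of clusters for both estimators; Bayesian
  coverage ≥ ML coverage in all eight populations; right-skewed
  (asymmetric) credible intervals at small cluster counts; ML breakdown
  concentrated at 5 clusters per condition. The systematic downward bias
  of the posterior median is asserted directly at populations 1–2 (where
  300+ replications give ≥3 MC-SE resolution) and across the grid via a
  per-population no-upward-bias bound plus a pooled z-score bound —
  48 replications per population cannot resolve a −5% bias individually,
  and the replication counts that could are out of desk-scale budget.

## What the synthetic conditions do and do not show

The generator *is* the study's data model: Gaussian components, exact
balance, correctly specified analysis model, no missingness. Passing
tests therefore demonstrate estimator behavior under ideal conditions —
undercoverage of delta-method intervals and ML breakdown at few clusters
are *optimistic* bounds for real data, which add non-normality and model
misspecification. Two caveats specific to this implementation: the norms
block values are a fixed convention (see above), so quantities driven by
the information content of the data — power, and the degree of
posterior-median shrinkage — can sit a few percentage points away from
results generated under a different norms configuration; and the
ML completion rule is an analogue of a closed-source original, so
convergence tallies are comparable in pattern, not cell-by-cell.
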