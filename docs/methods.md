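# Methods

## Model and measures

The package works with the two-level random-intercept logistic model:
individuals *i* nested in clusters *h*, binary outcome `Y_hi`,

```
logit π_hi = β₀ + β₁ x1_hi + β₂ x2_hi + α x_h + u_h,   u_h ~ N(0, σ²_u),
```

where `x1, x2 ~ N(0,1)` are individual-level covariates, `x_h ~ Bernoulli(p)`
is constant within a cluster, and `u_h` is independent of all covariates.
On the latent-variable view the level-1 residual follows a standard logistic
distribution, so its variance is fixed at `π²/3 ≈ 3.2899` — a property of
the link, not a parameter.

Four summaries of cluster structure are computed from `(α, σ²_u)`:

* **ICC** `= σ²_u / (σ²_u + π²/3)` — a strictly increasing bijection from
  `[0, ∞)` onto `[0, 1)`.
* **MOR** `= exp(√(2σ²_u) · Φ⁻¹(0.75))` — the median of the ordered odds
  ratios between covariate-identical individuals from two random clusters;
  always ≥ 1, equal to 1 only at σ²_u = 0.
* **IOR** at mass *m* `= exp(α ∓ √(2σ²_u) · z)`, `z = Φ⁻¹((1+m)/2)` — the
  central interval of the distribution of odds ratios across cluster pairs
  one unit apart on `x_h`. The interval is log-symmetric about α
  (`log L + log U = 2α`). The conventional mass is 0.80 but it is a free
  parameter here, since the 80% choice is conventional rather than
  principled.
* **SOI** `= Φ(α / √(2σ²_u))` — the fraction of those pairwise odds ratios
  exceeding 1. It satisfies the reflection identity
  `SOI(α) + SOI(−α) = 1` and the duality
  `1 ∈ IOR-m  ⇔  (1−m)/2 < SOI < (1+m)/2`.

**Quantile constants.** Defaults use full-precision quantiles
(Φ⁻¹(0.75) = 0.67448975…, Φ⁻¹(0.90) = 1.28155157…). The rounded constants
that circulate in applied papers are available as explicit MOR modes:
`printed_0p6745` (0.6745) and `printed_0p95` (the collapsed
`exp(0.95·√σ²_u)`, which differs from the exact form in the third decimal —
e.g. at σ²_u = 0.455 the exact MOR is 1.903 while the 0.95-form gives
1.898). Published numbers computed with the rounded forms are reproducible
only in these modes, so they exist for fidelity, not as defaults.

**σ²_u = 0 conventions.** Fitted variances can land exactly on the boundary,
so the measures treat zero variance as a documented limit rather than an
error: ICC 0, MOR 1, IOR degenerate at `(exp α, exp α)`, SOI the sign limit
(0 / 0.5 / 1 for α negative / zero / positive).

## Simulator

`simulate_dataset` draws, in a fixed order for reproducibility: all H
random effects `u_h ~ N(0, σ²_u)`, then the cluster covariates
`x_h ~ Bernoulli(p)` (once per cluster — the IOR/SOI definitions require a
cluster-constant covariate), then `x1, x2` for every row, then
`y ~ Bernoulli(expit(η))`. The true `u_h` (and on request the per-row
probabilities) are retained, so tests can verify that
`logit(π) − fixed part = u_h` holds row by row. Default fixed effects are
β₀ = 0.5, β₁ = −1.5, β₂ = 0.3, α = −0.3; cluster size is constant within a
condition. Degenerate clusters (all-0 or all-1 outcomes) are legal and
retained.

`application_preset` emulates the structure of a community-clustered child
health survey: 850 communities with sizes drawn from a Poisson(5.5)
truncated to [1, 15] (the simplest count model matching the target mean,
range and mode ≈ 6), σ²_u = 0.455, a binary community covariate with
coefficient log(1.21), and an intercept solved numerically (Gauss–Hermite
marginalisation + Brent root-finding) so the marginal prevalence is 0.63.
Individual covariates are included in the schema with zero coefficients:
the preset reproduces the nesting structure, outcome level and
between-community variance of such surveys — not their substantive
covariate effects, survey weights or spatial structure. Passing tests on
preset data therefore speak to the pipeline's behaviour under realistic
cluster-size imbalance, not to any real survey's estimates.

**Seed discipline.** Replicate *r* of condition `(H, N_h, σ²_u)` uses a
seed derived via `numpy.random.SeedSequence(base_seed, spawn_key=(H, N_h,
round(σ²·1e6), r))`, reduced below 2³¹. Any replicate is reproducible in
isolation, and grid results are identical serial or parallel.

## Maximum-likelihood fitter

The marginal likelihood integrates `u_h` out of each cluster's Bernoulli
likelihood. Integration is adaptive Gauss–Hermite: a damped Newton
iteration (the log-integrand is strictly concave in `u`) locates each
cluster's conditional mode, the curvature there sets the scale, and the
quadrature nodes are centred/scaled accordingly. One node is exactly the
Laplace approximation; the default 15 nodes agrees with dense trapezoid
integration to better than 1e-8 on small clusters and with a 25-node rule
to 1e-6 relative on moderate data. At σ_u = 0 the integral collapses and
the code evaluates the plain logistic log-likelihood directly.

Optimisation is L-BFGS-B on the mean log-likelihood (scaling by 1/n keeps
finite-difference gradients well conditioned) over `(β, α, σ_u)` with
`σ_u ∈ [0, 15]` — the standard-deviation scale rather than `log σ` so the
boundary is attainable. Initialisation is deterministic: an ordinary
logistic fit (statsmodels GLM) for the fixed effects and σ_u = 0.3.
When the optimiser stops at σ_u < 0.05 the fixed effects are re-polished at
σ_u = 0 and the better of the two log-likelihoods wins; a boundary fit
reports `σ̂²_u = 0` exactly, a `boundary` flag, and no standard errors
(the information matrix is singular there). Otherwise standard errors come
from the observed information, a central-difference Hessian of the marginal
log-likelihood. Non-convergence is reported via the `converged` flag, never
silently. Cluster order and row order within clusters do not affect the
likelihood (per-cluster sums are index-based), which is unit-tested.

The fitter was cross-checked against an independent implementation
(`lme4::glmer` with `nAGQ=15` via Rscript) on a moderate simulated dataset:
coefficients, σ̂², standard errors and log-likelihood agree to ~1e-5.

## Monte Carlo study

For each grid cell, R datasets are simulated and fitted, and each converged
fit contributes the nine quantities (β̂₀, β̂₁, β̂₂, α̂ and the four measures,
MOR/IOR in the exact-constant mode, matching the analytic true values used
as RMSE anchors). Aggregates are the per-quantity mean and

```
RMSE = sqrt( mean_r (estimate_r − true)² )
```

over converged replicates — the standard across-replicate definition.
Non-converged or errored fits are excluded from aggregates but counted
(`n_converged + n_failed = R` always); a cell with no convergences is
flagged unusable instead of aborting the grid.

One design point deserves emphasis: the per-condition summary stores means
of the *per-replicate* measures (the right object for bias and RMSE), while
the rendered estimates table recomputes its measure columns from the mean
`(α̂, σ̂²_u)` so that the table is internally consistent — its ICC/MOR/SOI/
IOR entries are exactly the closed forms applied to its own parameter
entries. The Jensen gap between the two conventions is far below display
precision at the grid sizes used.

Rendered CSV tables follow the published display precisions (3 decimals
for coefficients, MOR and the IOR upper limit; 4 for ICC, SOI and the IOR
lower limit). All outputs are deterministic down to the byte given a base
seed.

**Problem sizes.** The package supports the full factorial experiment
(clusters {10, 50, 100, 300, 500} × sizes {5, 20, 50, 100, 250} ×
variances {0.2, 0.5, 1.0, 1.5} × 1000 replicates). The test suite exercises
the same code at desk scale, chosen to keep Monte Carlo error interpretable
while running in minutes: 100 replicates for the single-cell bias check at
(H=100, N_h=50, σ²=0.5), 20 seeds for large-sample recovery at (H=500,
N_h=100), and 2–25 replicates for structural/determinism checks.

## Numerical choices and edge cases

* Newton mode-finding: steps clipped to ±4, gradient tolerance 1e-11,
  warm-started from the previous objective evaluation.
* Boundary decision: σ = 0 is preferred when its polished log-likelihood is
  within 1e-8 of the interior candidate, biasing ties toward the simpler
  model.
* Inputs with all-identical outcomes raise (non-identifiable intercept);
  fewer than two clusters raise; per-cluster separation is tolerated.
* Subnormal variances: `exp(√(2σ²)·c)` underflows to exactly 1.0 below
  σ² ≈ 1e-300; the measures still satisfy their invariants there.
* ICC interpretation bands: < 0.50 low, 0.50–0.75 moderate, 0.75–0.90 high,
  above very high; the edges 0.50 and 0.90 belong to the lower-named band's
  "between" range (0.50 → moderate, 0.90 → high).

## Known limitations

* Two levels only; random intercepts only (no random slopes, no crossed or
  three-level designs), no survey weights — the fitter targets the model
  the measures are defined for.
* No confidence intervals for the derived measures (delta method or
  bootstrap would be natural extensions).
* The published true-value table this package reproduces appears to carry
  two sub-display-precision rounding slips (its ICC at σ² = 0.2 prints
  0.0570 where the formula gives 0.0573, and two other cells are off by
  less than one unit in the last printed digit); the analytic values here
  are the formulas' own.
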