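# Methods

## Model

`mlrpower` estimates statistical power, by Monte-Carlo simulation, for the
two-level logistic regression model with a random intercept, a random slope
and a cross-level interaction:

    logit(pi_ij) = beta_0j + beta_1j * x_ij
    beta_0j = gamma00 + gamma01 * z_j + u0j
    beta_1j = gamma10 + gamma11 * z_j + u1j
    (u0j, u1j) ~ N(0, [[sigma0^2, sigma01], [sigma01, sigma1^2]])

with unit-level predictor `x_ij`, cluster-level predictor `z_j` and binary
outcome `y_ij ~ Bernoulli(pi_ij)`. The design is balanced: `N2` clusters of
`N1` units each.

On the latent logistic scale the unit-level residual variance is fixed at
pi^2/3 (the variance of a standard logistic variate), so the intraclass
correlation implied by a random-intercept variance sigma0^2 is
`sigma0^2 / (sigma0^2 + pi^2/3)`. The presets use sigma0^2 = pi^2/7 (ICC
0.3, "medium") and pi^2/3 (ICC 0.5, "large"); these ratios are exact
(3/10 and 1/2).

## Effect-size presets and scenarios

Coefficients are keyed to the predictor's type, not its level: binary
predictors carry 0.5 (medium) or 0.8 (large) on the log-odds scale,
continuous predictors 0.3 or 0.5, and the cross-level interaction 0.3 or
0.5. The random-slope variance is 0.3 (medium) or 0.5 (large). Two defaults
deserve note, since both are genuinely open choices:

- `gamma00 = 0`: the baseline incidence is 50% on the probability scale.
  It is configurable per scenario (`ScenarioSpec.with_fixed`).
- `sigma01 = 0`: intercept and slope effects are independent by default.
  This keeps the slope-variance likelihood-ratio test a clean
  one-degree-of-freedom comparison (see below). A `free_covariance` flag
  estimates sigma01, at the cost of the test adding two parameters.

Named scenarios (`case_preset`) cover a benchmark (balanced binary x,
standard-normal z), jointly degraded conditions (`case2`: unbalanced binary
x with skewed chi-square z; `case3`: the same distributions with levels
swapped), and two single-factor probes (normal x with extremely unbalanced
z; extremely skewed x with balanced z). Severity levels are moderate
(30% incidence / chi-square df 5, skewness sqrt(8/5)) and extreme
(10% incidence / chi-square df 1, skewness sqrt(8)).

## What the generator emulates — and a consequence worth knowing

`simulate_dataset` redraws everything per replication: z and (u0, u1) per
cluster, x per row, then `y ~ Bernoulli(expit(eta))`. Binary predictors are
i.i.d. Bernoulli(incidence) draws (an exact-split option exists for the
cluster-level predictor, since "30% of 110 clusters" is realizable
deterministically). Chi-square predictors are used **raw** by default —
mean df, variance 2·df — because empirical skewed covariates (income,
counts, exposure) do not arrive standardized; a `standardize` switch
rescales to mean 0, variance 1 for sensitivity analyses.

The raw default has a statistical consequence users should anticipate: a
raw chi-square(1) covariate has variance 2, so at a fixed coefficient it
carries *twice* the information of a standard-normal covariate, and power
for that coefficient can **increase** under "worse" skewness. Skewness per
se costs little at these effect sizes; what moves power is the predictor's
variance (and, for binary predictors, the incidence p through p(1-p)).
Relatedly, an uncentered cluster-level predictor appearing in both the main
effect and the product term induces strong collinearity between z and z·x
(correlation ~0.7 for balanced x), which inflates the variance of the
cluster-level main effect. These are properties of the model itself —
confirmed here against an independent mixed-model engine — not artifacts of
this implementation. Simulation studies that report the opposite ordering
have typically standardized their predictors, controlled the product-term
collinearity, or both.

The generator does not emulate: unequal cluster sizes, missing data,
predictor-predictor correlation, more than one predictor per level, or
more than two levels. Passing tests therefore say nothing about designs
with those features.

## Estimation

The marginal likelihood integrates each cluster's Bernoulli likelihood over
its random effects; there is no closed form under the logit link. We use
adaptive Gauss-Hermite quadrature: per cluster, the integrand's posterior
mode is found by a damped, vectorized Newton iteration (the integrand is
log-concave, so this is globally stable), nodes are recentred at the mode
and rescaled by the Cholesky factor of the inverse negative Hessian, and
the integral is accumulated by log-sum-exp. With one node per dimension
this reduces exactly to the Laplace approximation (verified against an
independently coded Laplace oracle at 1e-8). The default of 7 nodes per
dimension is a standard accuracy/speed compromise; on well-separated data
refining 7 -> 15 nodes moves the maximized log-likelihood by < 1e-3.

Optimization is L-BFGS-B on an unconstrained parameterization (raw fixed
effects; log standard deviations; atanh correlation when sigma01 is freed),
with `3-point` numerical gradients, `gtol = 1e-5` and box bounds
(log-SD in [-7, 3]) that keep the likelihood finite. Two starts are tried
before declaring nonconvergence: all-zeros, then a method-of-moments-style
start (plain-logistic fixed effects plus a cluster-logit variance guess).
Wald standard errors come from the observed information — a central-
difference Hessian of the marginal log-likelihood at the optimum; the
fixed-effect block of its inverse is invariant to the variance
reparameterization. Rows are pooled into per-cluster sufficient statistics
over the distinct values of x (exact for discrete predictors; a no-op for
continuous ones), which is what makes thousand-replication power runs
tractable on one core.

## Testing ladder

Fixed effects are tested by two-sided Wald z-tests. Variance components use
one-degree-of-freedom likelihood-ratio tests between adjacent models:

- sigma0^2: random-intercept model vs plain logistic regression;
- sigma1^2: intercept+slope model (sigma01 fixed at 0) vs intercept-only.

Statistics are floored at zero and referred to chi-square(1). Because the
null value lies on the boundary of the parameter space, this reference is
conservative (the asymptotic null is a 50:50 mixture of a point mass at 0
and chi-square(1)); the plain chi-square(1) reference is retained as the
conventional practice this toolkit models, and the conservatism is simply
inherited by the reported power.

## Power estimation

`estimate_power` aggregates replications, each simulating a dataset and
fitting the required models. Power per target is the share of *converged*
replications with p < alpha; the nonconverged count is always reported, so
estimation trouble (frequent at small N with rare predictor categories) is
visible rather than silently absorbed. Every replication is keyed by
(grid-cell index, replication index) through `SeedSequence` spawn keys: a
master seed fully determines the result, serial and parallel execution
agree bit-for-bit, and any scheduler may run replications in any order.
Each power estimate carries its binomial Monte-Carlo standard error
sqrt(p(1-p)/n).

The conventional full design (91 N1 values x 6 N2 values x 1000
replications per scenario) is supported but is a cluster-scale job. The
package's own validation runs use 200-300 replications on coarse grids
(2x2 corners of the N1 in [10,100], N2 in [10,110] region, plus the
largest cell at N1=100, N2=110), which bounds Monte-Carlo SEs at ~0.035
and keeps a full run on one core in the tens of minutes; `mlrpower power`
warns when fewer than 200 replications are requested.

## Numerical choices and degenerate inputs

- Mode finding: Newton with step-halving, gradient tolerance 1e-10,
  step clipped at 5 latent-scale units per iteration.
- PSD validation of the random-effects covariance uses the determinant
  test with a 1e-12 slack; simulation adds 1e-14 jitter before Cholesky so
  exactly-zero variances degrade gracefully to degenerate normals.
- Constant outcomes raise a degenerate-data error; fits on datasets with a
  single cluster are refused.
- A fit whose observed information is not positive definite is flagged
  nonconverged rather than reporting unusable standard errors.
- p-values are computed in log space (`log_ndtr`), so extreme z-statistics
  do not underflow to exactly 0.

## Known limitations

- Balanced designs only; power under uneven cluster sizes can differ.
- The Wald/LRT ladder models conventional practice; profile-likelihood or
  bootstrap inference for variance components is out of scope.
- Monte-Carlo power at 200 replications has ~3.5-point standard errors;
  research-grade runs should use 1000.
- Absolute power levels are sensitive to design choices that published
  rule-of-thumb tables often leave implicit (predictor standardization,
  centering of the product term, the baseline incidence gamma00). The
  defaults here are explicit and configurable; comparisons with external
  tables should first reconcile those choices.
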