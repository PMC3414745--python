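# Methods

## The setting

Each of N subjects, partitioned into k groups (k = 2 throughout the
simulation engine), yields responses y_ij at times t_ij. The package
targets data whose subject profiles are approximately linear in time, so
that three hypotheses exhaust the usual questions: no time effect, no
group effect, no group × time interaction. Three analysis routes are
implemented against the same hypotheses so that their operating
characteristics can be compared like for like.

## Summary-measure approach

Subject i is reduced to the OLS slope of y on t (rate of change) and the
mean of y (level). Under no interaction the group slope distributions
share a location; under no time effect the population mean slope is zero;
under no group effect the group mean-level distributions share a
location. Tests:

* time: one-sample t of all defined slopes against 0, df = (#slopes) − 1;
  slopes are pooled across groups (the null is about the overall mean
  slope), no group-stratified variant is offered.
* interaction / group: pooled-variance two-sample t (k = 2) or one-way
  ANOVA F (k > 2) on slopes / means. Rank variants use midranks with the
  asymptotic normal (Wilcoxon–Mann–Whitney, no continuity correction) or
  chi-square (Kruskal–Wallis) reference; no exact small-sample tables.
* permutation variant: group labels are permuted over subjects' summary
  values; the statistic is the corresponding parametric one; two-sided
  p = (1 + #{|T*| ≥ |T|}) / (1 + B), B = 9999 by default, seeded
  generator required. With B exhausting the label assignments this
  converges to the exact conditional p.

Subjects with fewer than two distinct times have no slope; they are
flagged, excluded from slope-based tests with a warning, and keep their
mean. The two-sample t is classical pooled-variance (a Welch option
exists but is not the default, to keep the reproduction path classical).

## Profile analysis (unstructured multivariate approach)

Responses must be balanced and complete on a shared grid (the
`data_model` pivot enforces this; incomplete subjects are never imputed,
only dropped explicitly via `complete_case_subset`). With C any
(m−1) × m full-rank matrix whose rows sum to zero — the adjacent
difference matrix by default; all statistics are provably invariant to
the choice, and the test suite asserts this numerically —

* parallelism: one-way MANOVA on d_i = C y_i; Wilks
  Λ = det(E)/det(E+H); Rao's F approximation (exact for k = 2, where it
  equals the two-sample Hotelling T², and for m − 1 ≤ 2). Requires
  N − k > m − 1, otherwise a feasibility error: with many time points
  and few subjects the pooled covariance of the transformed responses is
  singular and the approach simply cannot run. Wilks' Λ is the only
  MANOVA statistic implemented; Pillai etc. would add nothing on the
  k = 2 reproduction path where all coincide.
* time: one-sample Hotelling T² = N d̄ᵀ S⁻¹ d̄ on the pooled differences,
  F = (N−m+1)/((N−1)(m−1)) · T² on (m−1, N−m+1) df.
* group: delegated to the summary-mean test (more efficient than a
  MANOVA contrast of levels and identical to the SMA group test).

In the Monte Carlo engine the multivariate route is reported as a whole:
when N − k ≤ m − 1 both trend tests are flagged infeasible for that
replicate (the group test, which needs no wide pivot, still runs).

## REML linear mixed model

Model: y_i = X_i β + Z_i b_i + ε_i with fixed effects intercept, k−1
reference-coded group indicators, numeric time, and group × time;
b_i ~ N(0, G) with Z_i the intercept column (q = 1) or intercept and
time (q = 2, G unstructured); ε_i ~ N(0, R_i) with

* `ind`: σ²I — with a random intercept the marginal covariance is
  compound symmetric, V = σ_b²J + σ²I, intraclass correlation
  σ_b²/(σ_b²+σ²);
* `ar1`: σ²H, h_jj′ = ρ^|j−j′| over measurement *positions* (for the
  equally spaced grids this engine generates, position and time lag
  coincide up to the unit);
* `uns`: a free m × m SPD matrix indexed by position on the shared time
  grid; requires balanced complete data and enough observations to
  estimate m(m+1)/2 parameters. Note that with a free R the random
  intercept is not separately identified (R can absorb σ_b²J); the
  marginal covariance and hence all tests and criteria are identified,
  which is what the model menu compares.

Estimation maximises the REML log-likelihood
−½ Σ_i [log det V_i + r_iᵀV_i⁻¹r_i] − ½ log det(Σ_i X_iᵀV_i⁻¹X_i)
− ½(N_obs − p) log 2π with β profiled out by GLS at each step.
Parameterisation is unconstrained: log standard deviations, Fisher-z for
ρ, log-Cholesky factors for G and the unstructured R (diagonal on the
log scale). Optimiser: L-BFGS-B with numerical gradients, gradient
tolerance 1e−8, at most 500 iterations, parameters capped at ±12 on the
unconstrained scale; start values split the OLS residual variance evenly
between the intercept and the error. A covariance that fails its
Cholesky factorisation during the search returns a large finite penalty
that grows with ‖θ‖ (an infinite value would poison the finite-difference
gradient and stall the line search). A failed line search triggers up to
two restarts with a fresh Hessian approximation. Variance components may
hit the boundary (σ_b² → 0) with a warning, never an error. Subjects
sharing an observation-time pattern are vectorised together, so balanced
designs cost one m × m factorisation per objective evaluation.

Hypothesis tests are Wald F statistics. The default is **sequential**
(each term adjusted for the terms before it, in the order intercept,
group, time, group × time), computed as the squared entries of R β̂
where R is the upper Cholesky factor of cov(β̂)⁻¹; marginal (type-III)
tests are available via `test_type="marginal"`. Sequential is the
default because it is what the classical multilevel software (R's nlme,
whose inner–outer convention this module reproduces and against which it
is cross-checked in the test suite) prints, and the two are *not*
interchangeable in the misspecification experiments: under an AR(1)
truth with an `ind` working structure at m = 20 the sequential time test
rejects at ≈ 0.36 and the marginal at ≈ 0.39. The two coincide for the
last term (the interaction) and under the global null both are exactly
calibrated when the working structure is correct.

Denominator df follow the inner–outer rule: between-subject terms
(intercept, group) get N − p_between with p_between the number of fixed
columns constant within subject (2 for two groups); within-subject terms
(time, interaction) get N_obs − N − p_within (again 2). For the
two-group model this gives group: N − 2; time and interaction:
N_obs − N − 2.

AIC = −2ℓ_REML + 2d and BIC = −2ℓ_REML + d log N_obs with d = fixed
effects + free variance parameters (e.g. three groups, m = 14,
intercept + slope, `uns`: d = 6 + 3 + 105 = 114). BIC uses N_obs, not an
effective REML sample size; criterion values are therefore comparable
within this package but may differ by constants from other software, so
rankings rather than absolute values are the supported output of the
model menu.

## The data generator and the Monte Carlo study

`generate_dataset` draws from
Y_ij = β₀ + β₁X_i + β₂t_j + β₃t_jX_i + b_0i + ε_ij with two groups
(X ∈ {0,1}) of equal size n, the shared grid t_j = 2j (j = 1..m), normal
b_0i with SD 0.25, and jointly normal errors with R per structure, drawn
via Cholesky of R (distributionally identical to a sequential AR
recursion and simpler to verify by moment checks). Study defaults match
the published comparison: β₀ = 2, σ² = 0.5 and ρ = 0.7 for `ind`/`ar1`,
m ∈ {5, 10, 20}, n ∈ {5, 10, 30, 50}, within-subject effect sizes
shrinking with m (β₂ ∈ {0.020, 0.040} at m = 5 down to {0.005, 0.010}
at m = 20, β₃ likewise), α = 0.05.

The generating matrix for the `uns` (arbitrary-covariance) arm was never
published; `default_uns_matrix` is a documented stand-in — variances
uniform in [0.25, 1.0], correlations decaying geometrically with lag,
reproducible per (m, seed) — so `uns`-truth cells are qualitatively but
not numerically comparable to the published table, and they are excluded
from the numeric acceptance checks accordingly.

Randomness is counter-based: replicate r of configuration c under root
seed s uses `SeedSequence([s, c, r])`, making every cell independently
reproducible and trivially parallelisable. Per-replicate failures
(multivariate infeasibility, REML non-convergence) are recorded with
reason codes and excluded from the cell's rate — never replaced by a
fabricated p-value — with valid/failed counts reported per cell.

What the generator does *not* emulate: missing data, unequal group
sizes, non-normal errors, nonlinear profiles, and k > 2 groups. Passing
the simulation checks therefore says nothing about those regimes; the
analysis modules themselves do handle unbalanced long-format data (SMA,
LMM with `ind`/`ar1`) but their operating characteristics there are not
certified by this study.

## Problem sizes and tolerances

The acceptance script runs the summary-measure / multivariate cells at
1000 replicates and the two mixed-model cells at 250 and 500 replicates
(each of those replicates is a full REML fit); the package's own test
suite scales the same checks down to 120–400 replicates and widens the
Monte Carlo bands to three combined binomial standard errors. Numerical
comparisons between the two internal routes (e.g. Wilks vs Hotelling)
are asserted at relative 1e−8 to 1e−10; closed-form REML equalities at
1e−3 to 1e−4 (the optimiser's practical accuracy on these problems).

## Known limitations

* The `uns` mixed model requires a shared complete time grid; there is
  no factor-analytic or banded compromise for nearly balanced data.
* Denominator df are inner–outer only; Satterthwaite or Kenward–Roger
  corrections, which matter most for small unbalanced designs, are out
  of scope.
* The permutation variant permutes whole-subject summaries, which is
  exact for the group and interaction nulls but no permutation time test
  is offered.
* REML standard errors of variance components are not reported; the
  model menu compares fits by criteria, not by variance-parameter tests.
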