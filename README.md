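# linetrend

Analysis of **linear-trend repeated-measures data**: the same response
measured on each subject at several time points, in two or more groups,
where the scientific questions are

* **time** — does the response change over time at all?
* **group** — do the groups differ in overall level?
* **group × time (interaction)** — do the groups change at different rates?

The package implements, compares, and stress-tests three classical routes
to these hypotheses, for biostatisticians and applied researchers analysing
longitudinal experiments (growth curves, perfusion time courses, clinical
follow-up series):

1. **Summary-measure approach (SMA)** — reduce subject *i*'s response
   vector to its least-squares slope
   `b_i = Σ_j (t_j − t̄)(y_ij − ȳ_i) / Σ_j (t_j − t̄)²` and its mean
   `ȳ_i`, then apply ordinary univariate tests: a one-sample *t* of the
   pooled slopes against 0 (time), two-sample *t* / one-way ANOVA *F* of
   the slopes between groups (interaction) and of the means between groups
   (group), with Wilcoxon/Kruskal–Wallis and permutation variants.
   Works for unbalanced data and for any number of measurements.
2. **Unstructured multivariate approach (UMA / profile analysis)** —
   treat the *m* time points as a multivariate response with arbitrary
   common covariance: Wilks' Λ = det(E)/det(E+H) on contrast-transformed
   responses for parallelism (interaction), a one-sample Hotelling T² on
   adjacent differences for time, and the summary-mean test for group.
   Requires balanced complete data with N − k > m − 1.
3. **Linear mixed model (LMM)** — `y_i = X_i β + Z_i b_i + ε_i` fitted by
   REML, with a random intercept (optionally intercept + slope) and a
   selectable within-subject error covariance: independent (`ind`, which
   with a random intercept gives compound symmetry), first-order
   autoregressive (`ar1`, corr = ρ^|j−j′|), or unstructured (`uns`).
   Wald F tests use inner–outer denominator degrees of freedom; AIC/BIC
   support covariance-structure selection.

A Monte Carlo engine (`linetrend.simulation`) generates data from the
linear-trend random-intercept model
`Y_ij = β₀ + β₁X_i + β₂t_j + β₃t_jX_i + b_0i + ε_ij` under each error
structure and estimates empirical type-I error and power of every method,
reproducing the known pattern: the SMA stays calibrated under every error
structure, the multivariate tests are valid but conservative in power for
many time points, and a mixed model with a *misspecified* error structure
(e.g. `ind` working when the truth is `ar1`) badly inflates the type-I
error of the within-subject tests.

## Worked example

Simulate one dataset from the model above (m = 5 times t = 2, 4, …, 10,
30 subjects per group, AR(1) errors with ρ = 0.7, a real group effect
β₁ = 0.25 and a small interaction β₃ = 0.02), then analyse it:

```python
from linetrend import SimulationConfig, generate_dataset, write_long
ds = generate_dataset(
    SimulationConfig(m=5, n_per_group=30, beta=(2.0, 0.25, 0.05, 0.02),
                     structure="ar1", rho=0.7, sigma2=0.5),
    0, seed=42)
write_long(ds, "example.csv")
```

```sh
$ linetrend sma --input example.csv
     effect method statistic     value  df_num  df_den  p_value  reject
       time    sma         t  3.834491       1    59.0 0.000308    True
      group    sma         t -3.819692       1    58.0 0.000328    True
interaction    sma         t -1.543180       1    58.0 0.128226   False
```

The slope summary detects the time trend and the mean summary the group
difference; the small interaction is below the noise floor for the
summary route on this draw. The mixed model with the *correct* error
structure is a little sharper on the interaction:

```sh
$ linetrend lmm --input example.csv --structure ar1
...
     effect  method statistic     value  df_num  df_den  p_value  reject
      group lmm-ar1    wald_F 13.818093     1.0    58.0 0.000455    True
       time lmm-ar1    wald_F 20.829522     1.0   238.0 0.000008    True
interaction lmm-ar1    wald_F  3.905213     1.0   238.0 0.049291    True
```

`linetrend lmm --input example.csv --menu` fits all six
random-structure × error-structure combinations; on this dataset both
AIC and BIC correctly place the two `ar1` models ahead of the `ind` and
`uns` ones. `linetrend uma --input example.csv` runs the profile-analysis
tests, and `linetrend simulate` runs the full Monte Carlo grid.

## Layout

* `linetrend.data_model` — long-format dataset, wide pivot, completeness
* `linetrend.summary_measures` — slope/mean summaries and their tests
* `linetrend.profile_manova` — Wilks' Λ parallelism and Hotelling T² tests
* `linetrend.mixed_model` — REML engine, Wald F, AIC/BIC, model menu
* `linetrend.simulation` — data generator and Monte Carlo study runner
* `linetrend.cli_report` — `linetrend` command-line interface

See `docs/methods.md` for the statistical details and design choices.
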