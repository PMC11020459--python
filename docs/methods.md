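# Methods

## Model

For areas (zones) `i = 1..m`, with `n_i` surveyed units of which `y_i`
carry the indicator, the direct estimator is `p_i = y_i / n_i`.  The
area-level model has two stages:

* sampling model: `p_i | θ_i ~ N(θ_i, ψ_i)` with ψ_i treated as known;
* linking model: `g(θ_i) | β, σ²_ν ~ N(x_i'β, σ²_ν)`, `g` ∈
  {identity, log, logit}, `x_i` a `(p+1)`-vector with leading 1.

The identity link gives the matched Fay-Herriot linear mixed model; log
and logit give unmatched models whose sampling stage stays Normal on
the proportion scale while only the linking stage transforms θ.  Priors
are non-informative: `f(β) ∝ 1` and `σ²_ν ~ Uniform(0, upper)` with
`upper = 1` by default.  The uniform prior is placed on the variance,
not the SD; `upper` is configurable because logit-scale variances above
1 are plausible in other applications.

### Interpretation of ψ

ψ_i is the design variance of the survey proportion, computed as
`p̃_i (1 − p̃_i) / n_i` with the realized sample size in the
denominator.  Formulations that print the area population size N_i in
this denominator describe the finite-population variance of a census
proportion; at census scale those variances vanish and no smoothing
problem remains, so the survey-sampling reading is used and documented
here as an interpretation.

### Boundary cells

`y_i ∈ {0, n_i}` gives `p_i ∈ {0, 1}`, zero design variance and
undefined logs.  Such cells are replaced by `p̃_i = (y_i + 0.5)/(n_i + 1)`
before variance, CV, GVF and link computations, and flagged
(`adjusted`).  The rule applies only at the boundary so interior cells
are untouched.

## GVF

Design variances of small domains are themselves unstable, so the
log-log regression `log ψ_i = β₀ + β₁ log p̃_i + e_i`,
`e_i ~ N(0, σ²)`, is fitted by OLS over sampled areas (≥ 3 usable
areas, residual variance with the `n − 2` divisor) and back-transformed
with the smearing factor: `ψ̂_i = exp(σ̂²/2) exp(β̂₀ + β̂₁ log p̃_i)`.
The smearing factor corrects the retransformation bias
(`E[exp(e)] = exp(σ²/2)` for Gaussian e); on a perfect fit it is 1 and
the smoothed variances reproduce the raw ones exactly.

Note a structural limitation inherited from the functional form: since
`ψ = p(1−p)/n`, `log ψ` depends on `log n_i` as well as `log p`, and
the regression omits it.  When sample sizes vary widely (here 15–120)
the smoothed variance of a large-`n` area is biased up and of a
small-`n` area biased down.  The pipeline default remains `gvf`
(matching the workflow the method is normally run with, and the raw
variances are genuinely unstable); `raw` mode is retained and is what
the simulation studies aimed at the sampler itself use, precisely so
that GVF mis-calibration cannot confound them.

## MCMC

Metropolis-within-Gibbs on `(β, {μ_i}, σ²_ν)` with `μ_i = g(θ_i)`:

* **β** — exact draw from its Gaussian full conditional
  `N((X'X)⁻¹X'μ, σ²_ν (X'X)⁻¹)` (flat prior, equal linking variances).
* **μ_i** — the conditional factorises over areas, so all areas take a
  vectorised random-walk Metropolis step on the link scale; the target
  for area i is `log N(p_i; g⁻¹(μ_i), ψ_i) + log N(μ_i; x_i'β, σ²_ν)`.
* **σ²_ν** — full conditional ∝ `(σ²)^{-m/2} exp(−SS/2σ²)` on
  `(0, upper)`, i.e. a truncated inverse gamma; drawn by inverse CDF on
  the precision scale via regularized incomplete-gamma functions.

Defaults: 50,000 iterations, 5,000 burn-in, thinning 1, 2 chains
(chains seeded from spawned seed sequences, so runs are bitwise
reproducible given the seed).  Initialization: β from OLS of `g(p̃)` on
X, `θ_i = p̃_i`, `σ²_ν = upper/2`.  Proposal scales start at 0.5 and
adapt per area during burn-in only (Robbins-Monro, step `t^-0.6`,
target acceptance 0.44 — the 1-D optimum); adaptation freezes at the
end of burn-in so detailed balance holds for every retained draw.
Post-burn-in acceptance below 0.05 for any area is logged as a warning.
The β-update was validated against the closed-form GLS posterior of the
matched model with σ²_ν fixed (agreement within Monte-Carlo error at
20,000 draws).

## DIC

Deviance is defined on the sampling model only,
`D(θ) = −2 Σ_i log N(p_i; θ_i, ψ_i)`, which puts the three links on a
common scale.  `D̄` averages over retained draws; the plug-in `D̂` is
evaluated at the posterior mean of θ on the proportion scale (the scale
the deviance is defined on; a link-scale plug-in would differ by a
Jensen gap), `p_D = D̄ − D̂`, `DIC = D̄ + p_D = 2D̄ − D̂`.  In
`compare_links`, a link whose likelihood is undefined for the observed
direct estimates is reported inestimable instead of aborting the
comparison.

## Prediction for non-sampled areas

For each retained draw `(β, σ²_ν)` a fresh effect `ν* ~ N(0, σ²_ν)` is
drawn and `θ* = g⁻¹(x'β + ν*)`.  Summaries (mean, SD, equal-tailed 95%
interval, percent CV) are over these posterior-predictive draws, so a
non-sampled area's CV reflects coefficient *and* area-effect
uncertainty — it can never undercut the posterior SD of a sampled area
with the same covariates, and it is strictly positive, which is what
makes CVs for zero-sample zones reportable at all.

## Diagnostics

* **Bias diagnostic**: OLS of direct on HB estimates; (slope,
  intercept) near (1, 0) indicates design consistency.
* **Residual normality**: residuals `g(θ̂_i) − x_i'β̂` at posterior
  means; Shapiro-Wilk statistic/p-value plus Q-Q coordinates.
* **CV table**: {min, Q1, median, mean, Q3, max} of direct and HB
  percent CVs over sampled areas; the efficiency-gain column applies
  `100 (direct − HB)/direct` row-wise to the summary cells (the
  convention that reproduces published tables of this form);
  a per-area-gain alternative sits behind `per_area_gain=True`.
  Quantiles use linear interpolation between order statistics (the
  numpy/R type-7 default), fixed so the table is reproducible.
* Posterior SDs play the role of root-MSEs for HB estimates; `√ψ_i`
  for direct ones.

Sample SDs everywhere use the `ddof=1` convention.

## Synthetic generator

The generator emulates the structure the model assumes:
`ν_i ~ N(0, σ²_ν)`, `P_i = g⁻¹(x_i'β + ν_i)`,
`y_i ~ Binomial(n_i, P_i)`, with covariates drawn i.i.d. U(0, 1)
(census-share-like) and centred column-wise so the intercept stays
interpretable.  The default scenario matches the motivating study's
scale: m = 83 zones, 6 non-sampled, p = 8 covariates, logit link,
σ²_ν = 0.3243, β = (−0.94, 1.2, −0.8, 0.6, −0.5, 0.4, −0.3, 0.8, −0.6)
giving mean prevalence ≈ 0.28, `n_i ~` integer-uniform[15, 120]
(zone-level survey sample sizes are not published, so this range is a
realistic stand-in, not a claim about the survey), constant
`N_i = 2000`.  For log/identity links an inverse-linked proportion
outside (0, 1) raises an error listing the offending areas — silent
clamping would corrupt parameter-recovery studies.

What the generator does *not* emulate: the two-stage cluster/household
design and survey weights (areas are treated as simple random samples,
as the area-level model itself assumes), spatial correlation between
zones, covariate measurement error, and temporal drift between census
and survey.  Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to design
effects.

## Simulation-study sizes

The replicated studies in `fhsae.studies` use scaled-down MCMC budgets
chosen to keep a full battery within a few minutes on one core while
leaving Monte-Carlo error well below the effects examined: 5,000
iterations (1,000 burn-in) × 100 replicates for parameter recovery,
6,000 × 20 for link selection, 3,000 × 600 × 50 for the efficiency
direction, 20,000 retained draws for the GLS cross-check.  Batch-means
standard errors (40 batches) quantify MCMC error in the GLS comparison.

## Known limitations

* The Normal sampling model on `p_i` is an approximation to the
  binomial; at `n_i` as small as 15 it is visibly imperfect.  In
  recovery studies this shows up as a modest upward bias in the
  posterior mean of σ²_ν (~0.41 vs a generating 0.3243 at study scale;
  the gap shrinks to ~0.02 at n_i in the hundreds) and mild
  under-coverage of the intercept's credible interval: the plug-in
  `ψ_i = p̃_i(1−p̃_i)/n_i` is correlated with `p̃_i`, which re-weights
  areas systematically.  Slope coefficients are essentially unaffected.
* The flat-variance prior makes the posterior mean of σ²_ν skew high at
  moderate m even under a correctly specified Gaussian model.
* Log and logit links are near-indistinguishable when prevalences stay
  below ~0.5; DIC differences between them are then of order 1 and the
  selected link can vary from sample to sample.
* DIC is computed from the sampling model only; alternative plug-ins
  (link-scale mean) would shift `p_D` slightly.
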