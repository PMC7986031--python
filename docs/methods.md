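# Methods

`opendce` implements the statistical workflow of a choice-based conjoint
(discrete choice experiment, DCE) study: designing the choice tasks,
estimating individual-level part-worth utilities with a hierarchical Bayes
(HB) multinomial logit, summarizing attribute importance, and simulating
shares of preference for hypothetical products. The bundled presets emulate a
published DCE on the design of a contraceptive microarray patch (MAP) fielded
in New Delhi, India and Ibadan, Nigeria, so that the whole pipeline can be
validated end to end against known ground truth without any external data.

## Choice model

Respondent *i* facing task *t* with alternatives *j = 1..a* chooses
alternative *j* with multinomial-logit probability

    P_itj = exp(x_itj' β_i) / Σ_k exp(x_itk' β_i),

where `x_itj` is the effects-coded attribute profile of the alternative.
Effects coding gives each attribute with L levels L−1 columns; the reference
(last) level's utility is minus the sum of the others, so per-level utilities
sum to zero within each attribute. Declared first-order interactions add the
element-wise products of the two attributes' main-effect columns
((L_i−1)(L_j−1) columns per pair); a coded 2×2 block for two 3-level
attributes expands to a 3×3 grid with zero row and column margins.

Across respondents the coefficients follow

    β_i ~ MVN(Θ' z_i, D),     z_i = (1, covariates_i),

with covariates (age in years, education as a 0–5 ordinal, ever-use of a
modern contraceptive method as 0/1) centered internally so the intercept row
of Θ is the population mean. Priors: Θ flat; D inverse-Wishart with
`df = p + prior_df_add` (default add 5) and scale `prior_cov_scale · I`
(default 1) — weakly informative settings in line with common CBC/HB
practice.

## Sampler

One MCMC sweep performs:

1. **Θ | B, D** — conjugate matrix-normal draw around the multivariate
   least-squares solution.
2. **D | B, Θ** — inverse-Wishart draw with scale `S0 + R'R`.
3. **β_i | rest** — one random-walk Metropolis step per respondent,
   vectorized across respondents, with the proposal shaped by the current
   Cholesky factor of D. A scalar step size adapts toward `target_accept`
   (default 0.3) every 100 iterations *during burn-in only*, so the retained
   chain satisfies detailed balance.
4. **Joint translation move** — a single Metropolis proposal that shifts every
   β_i and the intercept row of Θ by the same vector δ, shaped by the pooled
   aggregate-MNL covariance. Because the within-group deviations are
   unchanged, all prior terms cancel and the move is accepted on the product
   likelihood alone. Without it, the population mean can only move through
   the slow drift of the individual updates — a well-known mixing pathology
   of hierarchical Gibbs samplers that is most severe when D is small (e.g.
   signal-free data), where it produces over-narrow credible intervals for
   the population mean. The move leaves the stationary distribution intact.

Chains initialize at the pooled aggregate-MNL estimate. All randomness flows
through a single seeded generator; a fixed seed yields bit-identical draws.
Non-positive-definite covariance draws are handled by jitter-and-retry; a
post-adaptation acceptance rate under 1% aborts with diagnostics.

Defaults are `n_burn = 10000`, `n_draws = 10000`, `thin = 10`. The test
suite and the acceptance script use shortened chains (typically 6000 burn-in,
3000 sampling iterations thinned by 5) — at the bundled study sizes
(~400–530 respondents, 15 or fewer coded parameters) these reproduce the
population-level quantities to well within the tolerances asserted, at about
half a minute per fit on one CPU.

## Aggregate model, design tools

The pooled multinomial logit (one shared β) is fitted by Newton's method with
analytic gradient and Hessian (convergence at gradient max-norm < 1e−8);
standard errors come from the inverse observed information. It backs the
design test (simulated uniform-random responders must produce near-zero main
effects with all standard errors below 0.05 — the usual conjoint-practice
precision bar, since the source studies publish no numeric threshold) and the
likelihood-ratio screen (χ² on 2ΔLL) that admits interactions or covariates
at p ≤ 0.05.

Designs are generated with a balanced-overlap strategy: each attribute's
levels are drawn by sampling without replacement from a level-balanced pool
spanning the whole design, so level frequencies are exact to within rounding
while tasks may still repeat a level across alternatives (overlap). Identical
full profiles within a task are repaired by redrawing one attribute from the
remaining pool. D-efficiency is evaluated at β = 0 (the utility-neutral
point, the standard default when no priors are available): with M the
aggregate-logit information matrix and p the number of coded parameters, the
reported score is `det(M)^(1/p) / n_tasks`, so replicating a design leaves
the per-task score unchanged. The minimum sample size follows the
Johnson–Orme rule of thumb `N > 500·c/(t·a)` with the bound treated as
attainable (c = 3, t = 10, a = 2 gives 75) and an optional multiplier for
the recommended doubling.

## Importance and market simulation

Per respondent, an attribute's importance is its utility range (max − min
level utility) as a percentage of the summed ranges; sample importance
averages these with a normal-approximation 95% CI (mean ± 1.96·SD/√n).
Importance uses the posterior-mean individual utilities (the industry
convention) and main effects only — interaction utilities are excluded from
the ranges, since the source studies report importances for the named
attributes and leave the treatment of interactions unstated. Respondents
with all-zero ranges receive uniform importances plus a warning rather than
being dropped.

Market simulation scores each product profile (one level per in-design
attribute, interactions included via the coded profile vector) for each
respondent. The default first-choice rule gives each respondent one vote,
split equally over tied argmax profiles for determinism; a logit
(share-of-preference) rule is provided for sensitivity analysis. The
relative gain of a target over a reference profile is
`100·(s_t − s_r)/s_r`.

## Synthetic populations and presets

The generator draws covariates (truncated-normal age, categorical education,
Bernoulli(0.5) ever-use matching the stratified recruitment), coefficients
β_i ~ MVN(Θ'z_i, D), and choices from the individual logit — exactly the
estimator's assumed data-generating process, with the truth retained for
scoring. Three presets reproduce the published studies' structure: `india`
(six attributes, duration×menstruation interaction, n = 496),
`nigeria_sample1` (six attributes, n = 530), `nigeria_sample2` (five
attributes, menstruation out of design, n = 416).

Preset population means take the published per-level utilities (first L−1
levels of each attribute; the published rows sum to ≈0, confirming effects
coding). The coded covariance is block-diagonal by attribute, with each
block's off-diagonal chosen so the implied SD of *every* expanded level —
including the reference level — matches the published SD column exactly
(a diagonal coded covariance would inflate reference-level SDs by up to
~30%). Interaction cells use their published SDs on the diagonal. Preset
covariate effects are zero, matching the published finding of no substantial
preference variation by age, education or ever-use.

Published utilities sit on a commercial-software scale whose absolute logit
magnitude is unrecoverable. Each preset divides the table by a calibration
factor — 25 (india), 21 (nigeria_sample1), 19 (nigeria_sample2) — chosen
once so that simulating a study and re-estimating it reproduces the published
root-likelihood fit statistic (RLH ≈ 0.8). The factor is an explicit,
user-overridable argument, and first-choice market shares and truth-level
importances are invariant to it.

### What the presets do and do not emulate

They emulate the study dimensions, the published population means and
per-level SDs, realistic covariates, and a fit level matching the published
RLH. They do **not** capture cross-attribute correlations of individual
utilities (unpublished), non-normal heterogeneity, response styles, or item
nonresponse. Consequences observed in validation:

- Attribute-importance profiles and orderings reproduce the published ones
  closely (menstruation ≫ duration > rest for the six-attribute samples;
  duration first for the five-attribute sample).
- The published *simulation* result — the improved design (small, 6-month,
  painless, one-day rash, foot) being chosen "nearly 50% more" than the
  reference (medium, 3-month, wrist, light prick, three-day rash, irregular
  period) — is **not** reproduced: under an MVN population with the published
  marginal means and SDs, the improved design wins for ~75% of respondents at
  the true coefficients (a gain of ~200%, scale-invariant under the
  first-choice rule), and more after estimation shrinkage. Matching a 60/40
  split would require the cross-respondent SD of the utility difference to be
  about three times what the published SDs imply, pointing to utility
  correlations (or a richer simulated product set) in the original analysis
  that the published table does not determine. The package reports the gain
  it computes; treat preset-based gains as upper bounds on product-design
  separation rather than calibrated market predictions.

## Numerical and degenerate-input conventions

Softmax probabilities subtract the row maximum before exponentiation, so
probabilities are translation-invariant and cannot overflow. Ties in
first-choice simulation split votes equally. Degenerate designs (an
attribute that never varies, collinear interaction columns) raise an
"unidentified design" error naming the offending columns, found via the
information-matrix null space. Respondents with all-identical choices are
retained — the hierarchy shrinks them — never dropped. Level indices are
1-based in files (conjoint-software convention) and 0-based in memory; the
fixed comprehension task is stored, flagged, and always excluded from
estimation.

## Known limitations

Individual-level precision is bounded by the 10 binary tasks per respondent:
individual β_i correlate ~0.6–0.8 with truth while population means recover
at r > 0.95. The draw-averaged RLH plateaus near 0.77–0.78 at these study
sizes regardless of utility scale (individual posterior uncertainty bounds
it), slightly below point-estimate RLH. The covariance prior is fixed rather
than hierarchical; mixture-of-normals upper models, monotonicity constraints
and randomized-first-choice simulation are out of scope.
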