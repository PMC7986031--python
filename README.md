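# opendce

Design, hierarchical Bayes estimation and market simulation for discrete
choice experiments (DCEs), with a synthetic-respondent generator for
end-to-end validation.

DCEs (choice-based conjoint studies) ask respondents to choose repeatedly
between hypothetical products described by attributes — for example a
contraceptive microarray patch (MAP) varying in application pain, rash
duration, body location, patch size, duration of protection and effect on
menstruation. `opendce` covers the full stated-preference workflow used in
such studies:

- **Sample sizing** by the Johnson–Orme rule of thumb, N > 500·c/(t·a).
- **Design**: randomized balanced-overlap choice designs, D-efficiency at the
  utility-neutral point, and a design test that fits simulated random
  responders and checks main-effect standard errors.
- **Estimation**: an individual-level multinomial logit with a multivariate
  normal population layer, β_i ~ MVN(Θ′z_i, D), estimated by MCMC
  (conjugate updates for Θ and D, adaptive random-walk Metropolis for each
  β_i, plus a joint translation move for fast population-mean mixing);
  covariates enter the population mean. Fit is summarized by root likelihood
  (RLH) and percent certainty.
- **Preference analysis**: per-respondent relative attribute importance
  (utility range as a share of the summed ranges), sample means with 95%
  CIs, and subgroup contrasts.
- **Market simulation**: first-choice (and logit) shares of preference for
  hypothetical product profiles and relative gains versus a reference
  design.
- **Synthetic data**: populations with known Θ, D and covariate
  distributions, including three presets parameterized from published
  MAP-study utility tables (India n=496, Nigeria n=530 with six attributes;
  Nigeria n=416 with five).

The library is organized as scikit-learn-style estimators
(`MultinomialLogit`, `HierarchicalBayesLogit` with `fit` and trailing
underscore attributes); module-level functions wrap them, and a `dce` CLI
wraps the modules. See `docs/methods.md` for the model, priors, sampler and
calibration details.

## Worked example

Simulate the six-attribute India-style study, fit the hierarchical model,
and summarize importances and a product comparison:

```python
import opendce as od

# 1. sample size: c=3 levels max, t=10 tasks, a=2 alternatives
print(od.min_sample_size(3, 10, 2))        # -> 75

# 2. synthetic study from the published-utility preset (496 respondents)
dataset, truth, beta_true = od.generate_study("india", seed=2026)
cm = od.build_design_matrix(dataset)
X, y = cm.respondent_tensors(dataset)

# 3. hierarchical Bayes fit (shortened chain; defaults are 10k/10k)
est = od.HierarchicalBayesLogit(n_burn=6000, n_draws=3000, thin=5, seed=1)
est.fit(X, y, Z=dataset.covariate_matrix(), labels=cm.labels)
print(od.fit_statistics(est.posterior_, X, y))
# -> FitStatistics(rlh=0.796, percent_certainty=0.671)

# 4. attribute importance (percent of total utility range, mean over women)
pu = od.point_utilities(est.posterior_, cm)
imp = od.mean_importance(od.importance_from_utilities(pu, dataset.spec))
print(imp.table.round(1))
#       attribute  mean_importance  ci_low  ci_high
#            pain              7.6     7.2      7.9
#            rash              9.1     8.7      9.6
#        location              5.1     4.8      5.5
#            size              5.4     5.1      5.7
#        duration             14.4    13.7     15.1
#    menstruation             58.3    57.2     59.5

# 5. market simulation: improved vs reference design, menstrual effect equal
ideal = od.ProductProfile("ideal", {
    "size": "small", "duration": "6 months", "pain": "no pain",
    "rash": "one-day rash", "location": "foot", "menstruation": "irregular"})
ref = od.ProductProfile("reference", {
    "size": "medium", "duration": "3 months", "pain": "light prick",
    "rash": "three-day rash", "location": "wrist", "menstruation": "irregular"})
res = od.share_of_preference(est.coef_, [ideal, ref], cm)
print(res.to_frame().round(3))
#      profile  share
#        ideal  0.915
#    reference  0.085
print(od.preference_gain(res, "ideal", "reference"))   # -> 981.0
```

Numbers above are from the exact calls shown (chain seeds included). The
menstruation attribute dominates (~58% of preference weight) with duration a
distant second — the pattern that drives the preset populations — and RLH ≈
0.80 means the model assigns the observed choice a geometric-mean probability
of about 0.8 per task (0.5 would be chance). In the two-product comparison
the improved design is preferred by nearly every simulated respondent; see
`docs/methods.md` on why synthetic populations built from published marginal
utilities overstate this separation relative to the published "nearly 50%
more frequently".

The same pipeline is available from the shell:

```bash
dce samplesize --c 3 --t 10 --a 2
dce synth --preset india --seed 7 --out-dir fixtures/
dce design --spec fixtures/spec.json --versions 10 --seed 1 --out design.csv
dce test-design --spec fixtures/spec.json --design design.csv --n 300 \
    --seed 2 --report diag.json
dce fit --spec fixtures/spec.json --design fixtures/design.csv \
    --responses fixtures/responses.csv --seed 3 --out fit
dce importance --utilities fit_utilities.csv --spec fixtures/spec.json \
    --out importance.csv
dce simulate --utilities fit_draws.npz --spec fixtures/spec.json \
    --profiles profiles.json --reference reference --out shares.csv
```

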