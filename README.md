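# pestmix

Residential pesticide-mixture exposure assessment and two-stage Bayesian
hierarchical modeling for epidemiologic cohorts.

## The problem

Children growing up in intensive agricultural regions are potentially
exposed to many pesticides at once.  Regulatory use-reporting databases
record every agricultural application at the land-survey-section level
(what, where, when, how many kilograms), which makes it possible to build a
*proximal use* exposure metric — the wind-weighted kilograms of each
pesticide applied within 1 km of a participant's home during a critical
developmental window — without biomarkers.  But the resulting exposure
variables are strongly correlated (rank correlations of 0.4–0.9 within the
organophosphate class), so single-pollutant regressions suffer copollutant
confounding while fully mutually adjusted regressions are unstable.

`pestmix` implements the standard epidemiologic answer to both problems for
cohorts with repeated behavioral outcomes (T-scores, mean 50 / SD 10, at two
adolescent visits):

1. **Exposure engine** — converts section-level application records,
   residential histories, and daily wind roses into per-participant
   exposures.  Each application inside the window is attributed to the
   residence occupied that day, weighted by the exact fraction of the
   section's area inside the 1-km buffer and by the fraction of time the
   wind blew from the section's compass sector (8 sectors, nearest
   meteorological station).  Totals are log2(kg + 1)-transformed so a
   regression coefficient reads "per two-fold increase in use".  A
   three-criterion filter (evidence of neurotoxicity, > 4,500 kg used
   countywide, used near ≥ 50% of homes) picks the analyzable pesticides.

2. **Two-stage hierarchical model** — first stage, a linear mixed model
   over all exposures simultaneously with a subject random intercept across
   visits:

       E[Y | X, W] = α + Xβ + Wγ + u,   u ~ N(0, σ_u²),  ε ~ N(0, σ²)

   second stage, an exchangeability structure on the exposure coefficients:

       β = Zπ + δ,   δ ~ N(0, τ²I)

   where Z maps pesticides to groups expected to act similarly (the primary
   Z pools only classes with more than one member — the organophosphates —
   and leaves the rest vague; sensitivity variants pool all classes or use
   diethyl/dimethyl chemistry plus a benchmark-dose potency column).  τ is
   fixed a priori from the judgment that effects lie within ±5 T-score
   units: `tau_from_half_width(5, 0.95) ≈ 2.551`.  All full conditionals
   are conjugate, so the model is fit by a bespoke block-Gibbs sampler that
   is testable update-by-update against closed forms, with Geweke,
   Gelman–Rubin, and autocorrelation diagnostics, plus an REML mixed-model
   comparator (no second stage) for sensitivity.

3. **Synthetic cohorts** — a Gaussian-copula generator reproduces the
   marginal quantiles, zero inflation, and blockwise rank-correlation
   structure of realistic exposure data, plus covariates and two-visit
   outcomes from the first-stage model with known ground truth, for
   calibration and recovery studies.

## Worked example

```python
from pestmix.simulate import SimulationConfig, simulate_study
from pestmix.design import assemble_design, build_design_z, PriorConfig
from pestmix.sampler import MCMCConfig, run_mcmc, summarize
from pestmix import catalog as cat

study = simulate_study(SimulationConfig(n_subjects=600, seed=3))
pests = cat.prenatal_pesticides()          # 11 pesticides, 6 OPs
design = assemble_design(study.exposures, study.covariates, study.outcomes,
                         "prenatal", "maternal", "score", pests)
z = build_design_z(design.x_names, cat.default_catalog(), variant="primary")
chains = run_mcmc(design, z, PriorConfig(tau=2.5),
                  MCMCConfig(n_iter=5000, n_burn=1000, seed=1))
summary = summarize(chains, params=[f"beta[{p}]" for p in pests])
print(summary.formatted().head(3))
```

prints (posterior median and 95% credible interval, in T-score units per
two-fold increase in use):

```
parameter
beta[acephate]        4.5 (4.0, 5.0)
beta[chlorpyrifos]    5.3 (4.7, 5.8)
beta[diazinon]        2.1 (1.6, 2.7)
```

For this seed the generating truths were 4.56, 5.26, and 2.21: each interval
covers its truth, and the pooled organophosphate coefficients are shrunk
toward their fitted class mean.  The same flow is scriptable end-to-end:

```bash
pestmix simulate --n-subjects 600 --seed 3 --out sim/
pestmix fit --config cfg.yaml --out results/
pestmix report --results results/ --out combined.csv
```

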