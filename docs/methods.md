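# Methods

## Exposure model

The exposure metric is wind-adjusted proximal agricultural use.  For a
participant, pesticide, and exposure window (prenatal: the 273 days ending
at birth; postnatal: birth to the 5th birthday),

    raw_kg = Σ_applications  kg × area_fraction × wind_weight

summed over reported applications whose date falls inside the window and
inside an occupied residence interval.  Conventions, each recorded in the
output metadata sidecar:

* **Coordinates** are consumed as projected planar meters (UTM-like);
  geocoding and datum conversion are upstream concerns.
* **Apportionment.**  A survey section is an axis-aligned square (default
  side 1,609 m) centered on its reported centroid.  The default weight is
  the exact fraction of the square's area inside the 1-km disc around the
  residence (shapely polygon intersection, 256 segments per quadrant;
  area error < 1e-4).  A `centroid` mode (all-or-nothing by centroid
  distance) is available as a config switch.
* **Wind weighting.**  Sectors are the 8 compass points, 45° wide, centered
  on N, NE, …, NW, bearings clockwise from north, boundaries at 22.5°
  offsets; a coincident centroid maps to N.  The weight is the
  window-average daily proportion of time the wind blew *from* the
  section's sector at the nearest station (Euclidean distance, lexicographic
  tie-break).  By default weights are the raw proportions, so a uniform
  rose contributes a factor of exactly 1/8; `wind_weight_scale = times8`
  rescales so a uniform rose reproduces the unweighted buffer total.  The
  choice shifts the log2 exposure by an additive constant and cancels in
  regression slopes, which is why both are supported and neither is
  privileged.
* **Multiple residences** are resolved by day-of-application attribution:
  an application counts against the residence occupied on its date.
  Applications inside the window but outside every occupancy interval are
  skipped and counted in the log.
* **Transform.**  Exposures enter the model as log2(raw_kg + 1).  The +1
  offset keeps zero use at exactly zero on the transformed scale (observed
  quantile tables show exact 0.00 entries for several pesticides, which is
  only consistent with an offset transform) while preserving the
  "per two-fold increase" reading asymptotically: doubling raw use adds
  1 − O(1/raw_kg) to the transformed value.
* **Selection filter.**  A pesticide is analyzable when it is neurotoxic,
  had strictly more than 4,500 kg applied countywide in the reference year,
  and was used within the buffer of at least 50% of participants
  (inclusive boundary).

## Statistical model

First stage, for subject i at visit v:

    Y_iv = α + X_i'β + W_iv'γ + u_i + ε_iv,
    u_i ~ N(0, σ_u²),  ε_iv ~ N(0, σ²)

with all pesticide exposures entered simultaneously and unstandardized
(log2 scale), so β_j is the change in T-score per two-fold increase in use
of pesticide j, mutually adjusted.  Second stage:

    β = Zπ + δ,  δ ~ N(0, τ²I)   (hierarchical rows)
    β_j ~ N(0, v₀)                (vague rows, v₀ = 10⁶)

Z variants:

* **primary** — only classes with more than one member are pooled (the
  organophosphates: 6 prenatally, 7 postnatally with naled); every other
  pesticide keeps a vague direct prior.  A singleton group column with a
  vague π is mathematically identical to a vague direct prior on β, and is
  implemented as the latter.
* **class** — one indicator column per chemical class (OPs, carbamates,
  pyrethroids, neonicotinoids, fungicides, herbicides), all rows
  hierarchical.
* **chemistry** — OP rows get diethyl/dimethyl indicators plus a potency
  covariate from the benchmark dose (BMD10).  The functional form is
  configurable (−log BMD10 by default, or 1/BMD10, or raw), standardized to
  mean 0 / SD 1 across the OPs, because the appropriate scale for a potency
  covariate is genuinely open.  The catalog's BMD10 values are synthetic
  placeholders on a realistic mg/kg/day scale; they exercise the structure,
  not the toxicology.
* **none** — all coefficients vague (the no-second-stage limit).

Postnatal models append the 11 prenatal exposures as adjustment columns with
their own Z block (their OP column and the postnatal OP column are distinct
second-stage parameters) sharing the same τ; they are treated as nuisance
and not reported by default.  Sex-interaction models append pesticide × girl
columns, and every pesticide coefficient then becomes hierarchical (class
pooling) since all of them benefit from shrinkage once the interaction halves
the information per coefficient; sex-specific effects are
β_boy = β_main and β_girl = β_main + β_interaction from the joint posterior.

**Priors.**  α, γ, π ~ N(0, 10⁶); σ², σ_u² ~ inverse-gamma(0.001, 0.001);
τ is fixed a priori.  The default τ places 95% of a mean-zero normal inside
±5 T-score units (half an SD of the normative scale):
τ = 5 / Φ⁻¹(0.975) ≈ 2.551.  The coverage multiplier is configurable because
"effects lie within ±5" does not by itself pin the mass assigned to that
interval; 95% is this package's declared reading.

**Covariates** are a fixed list (no data-driven selection): maternal age,
years in the US (3 levels), education (3 levels), marital status, maternal
depression, child sex, exact age at assessment, HOME z-score, poverty
status, and language of interview for maternal-report outcomes only.
Categoricals are reference-coded against the first listed level.

## Sampler

A bespoke block-Gibbs sampler rather than a generic PPL backend, so every
full conditional is testable against its closed form:

1. (α, β, γ) jointly: multivariate normal with precision D'D/σ² + P₀ where
   P₀ is the diagonal prior precision (1/τ² on hierarchical rows, 1/v₀
   elsewhere) and prior mean Zπ on hierarchical rows;
2. u_i: independent normals, precision n_i/σ² + 1/σ_u²;
3. π: conjugate normal regression of the hierarchical β on Z;
4. σ², σ_u²: inverse-gamma updates;
5. (impute mode only) missing Y redrawn from the predictive.

Defaults are 50,000 iterations after 10,000 burn-in, one chain, no thinning
(chain count and thinning are declared defaults, not estimates of anything);
4 chains when Gelman–Rubin is wanted.  Chains are reproducible bit-for-bit
under a fixed seed (per-chain seeds spawned from a root SeedSequence; the
pipeline derives per-run seeds from a master seed by fixed offsets).
Rank-deficient designs are rejected up front with the names of the
collinear columns (QR diagonal test).

**Missing outcomes.**  Rows with missing Y are dropped from the likelihood;
subjects keeping at least one visit keep their random intercept.  Under
this model that is exactly equivalent (up to Monte Carlo error) to treating
missing values as latent draws, and the latent-imputation mode is retained
solely so the equivalence is a testable property rather than a claim.

**Summaries** are posterior medians with equal-tailed 95% credible
intervals (linear-interpolation quantiles, not HPD), formatted
"median (lower, upper)" per pesticide; effective sample size uses Geyer's
initial-positive-sequence rule on FFT autocorrelations.

## Diagnostics

* **Geweke z**: difference of means of the first 10% and last 50% of a
  chain over the square root of the summed spectral-density-at-zero
  variance estimates.  The spectral estimator is a Bartlett-windowed
  autocovariance sum with lag truncation L = n^(1/3), fixed for
  reproducibility; its null rejection rate at |z| > 1.96 calibrates to
  5% ± 1.5% on iid chains.  Segments numerically constant to machine
  precision score 0.
* **Gelman–Rubin**: the classic √(((n−1)/n·W + B/n)/W) over ≥ 2 equal-length
  chains.  Conventional pass flags: |z| < 1.96, R-hat < 1.1 (no thresholds
  are inherited from anywhere; these are the field's conventions).
* **Autocorrelation** by FFT, lag 0 ≡ 1; trace/ACF/density panels are
  emitted as PNGs on request.

## Frequentist comparator

The identical first-stage model fit by REML (statsmodels MixedLM) with Wald
95% confidence intervals, no second stage.  Non-convergence is flagged on
the returned fit, not raised.  With one row per subject the random
intercept is unidentified and the fit collapses to OLS, which is used as a
test oracle.

## Synthetic cohorts

The generator emulates the features of real exposure data that matter to
the estimator, with everything configurable and defaults chosen once to
mirror a realistic cohort:

* **Exposures**: Gaussian copula with blockwise Spearman targets (0.6
  within a chemical class, 0.3 across classes — chosen to sit inside the
  reported 0.4–0.9 within-OP range; the cohort's exact correlation
  matrices are not public, so block targets are a declared stand-in).
  Spearman targets are converted to the copula scale by r = 2·sin(πρ/6).
  Non-positive-definite targets are repaired by eigenvalue clipping with
  the perturbation norm logged.  Marginals are shaped by a monotone
  piecewise-linear quantile map through per-pesticide quartile/maximum
  targets on the log2(kg+1) scale, with a point mass at zero whose size is
  inferred from which quartiles sit exactly at zero (25% when P25 = 0, 50%
  when P50 = 0, else 2%).
* **Covariates**: categorical draws at the bundled cohort frequencies
  (51.3% girls, 81.9% married, 44% ≤ 6th-grade education, …), maternal age
  ~ N(26, 5.9) clipped to [18, 45], HOME z-score ~ N(0, 0.9).
* **Outcomes**: Y from the first-stage model with α = 50, σ_u = 6,
  σ_ε = 8 (marginal noise SD 10, between-visit ICC 0.36), visits at ages
  ≈ 16.3 and ≈ 18.05, second-visit missingness 20% (≈ the 478/595 retention
  of the emulated cohort), n = 600 subjects.  True β are drawn from the
  class-structured prior: class means π ~ N(0, 2²), hierarchical
  β = π + N(0, τ²) with τ_true = 2.5, vague-row β ~ N(0, 2.5²).

What the generator does **not** emulate: spatial autocorrelation between
neighbors, exposure measurement error, informative missingness, non-normal
outcome tails, and time-varying covariates.  Passing recovery tests
therefore demonstrate internal calibration of the estimator under its own
assumptions — not robustness to the violations above.

## Validation studies and problem sizes

`pestmix.validation` packages the two headline simulation studies:

* **Coverage** — 200 cohorts at full scale (n = 600), refit with 5,000
  post-burn-in iterations after 1,000 burn-in; the shortened chains relative
  to the production default are ample here because the conjugate blocks mix
  within a few dozen iterations (lag-1 autocorrelations < 0.2), and the
  study pools 2,200 intervals.  Empirical 95%-interval coverage for
  exposure coefficients should land in the low-to-mid 90s.
* **Shrinkage** — 200 cohorts at n = 300 with 2,500 + 500 iterations,
  comparing hierarchical posterior medians to REML estimates: under
  class-structured truths the hierarchical fit has no worse mean squared
  error and narrower intervals on average.  The smaller per-replicate size
  is the package's choice for a study whose conclusion is a mean inequality
  over replicates, not a per-fit quantity.

## Known limitations

* The exposure engine consumes tabular section centroids, not real survey
  shapefiles; sections are idealized axis-aligned squares.
* Wind adjustment uses direction frequencies only — no wind speed, drift
  modelling, or decay with distance inside the buffer.
* Outcomes must be (conditionally) normal; no robust or generalized
  variants.
* The bundled catalog's BMD10 potency values are placeholders (see above);
  chemistry-Z results on bundled data exercise plumbing only.
* The Gibbs sampler assumes the stated conjugate structure; swapping in a
  non-conjugate prior requires a different backend (a config hook exists,
  only the bespoke sampler ships).
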