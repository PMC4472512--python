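# Methods

## The model

`commocc` fits a hierarchical multi-species, multi-season site-occupancy
model to roadside point-count monitoring data. Survey routes of 30 points
(1 km apart) are partitioned into consecutive *sites* of k = 5 points; the
five points of a site act as spatial replicates for estimating detection.

For species *i*, site *j*, year *t* the latent occupancy state is Bernoulli,

```
z(j,i,t) ~ Bern(psi_jit)
logit psi_jit = u(i,t) + a1(i) lat(j,t) + a2(i) long(j,t) + a3(i) soy(j,t)
              + a4(i) corn(j,t) + a5(i) per_past(j,t) + a6(i) forest(j,t)
```

and the observation at point *k* is Bernoulli conditional on presence,

```
y(j,k,i,t) ~ Bern(p_jkit * z(j,i,t))
logit p_jkit = v(i,t) + b1(i) p_fors(j,k,t)
```

Marginalizing z gives the zero-inflated binomial site likelihood
`psi * prod_k p^y (1-p)^(1-y) + (1-psi) * 1{all y = 0}` implemented in
`model.site_marginal_loglik` (verified against exhaustive latent-state
enumeration in the tests).

The intercepts are random time effects, `u(i,t) ~ N(mu_u(i), sig_u(i))`
(likewise v), absorbing year-to-year variation (climate, observers) not
captured by land cover. Species-level intercept means and all slopes are in
turn draws from community normal hyper-distributions, e.g.
`mu_u(i) ~ N(mu2_u, sig2_u)`, `a3(i) ~ N(mu_a3, sig_a3)`. This lets rarely
detected species borrow strength from their group. Covariate slopes are
modelled hierarchically by default; `PriorSpec(pooling="independent")`
switches to independent wide-normal priors per species (this mode is also
what the single-species toy oracle integrates).

### Priors

The prior families are deliberately weak and configurable
(`PriorSpec`): Normal(0, 10) on every community hyper-mean on the logit
scale, Uniform(0, 10) on every standard deviation (species level and
community level). On the logit scale a sd of 10 is effectively flat over
any plausible probability.

## Preprocessing rules (`occdata`)

* **Site partitioning** — consecutive blocks of `points_per_site` points;
  rejects non-divisible geometries.
* **LULC aggregation** — a site-year's category proportion is the summed
  point cover of that category divided by the site's total classified cover.
  When every point's categories sum to one this is the plain per-point mean;
  when no cover was recorded the covariate is missing. We chose the
  renormalized reading because it is the only one well defined for partially
  classified points.
* **Covariate screening** — pairwise Pearson |r| > 0.5 (pooled complete-case
  site-years) discards the covariate with the smaller mean landscape
  representation. The greedy pass runs in decreasing representation order,
  which makes the result order-independent when means are distinct.
  Zero-variance covariates are discarded outright.
* **Species filter** — species with fewer than `min_obs = 200` total
  detections over the full period are dropped (boundary inclusive: exactly
  200 is kept).
* **Coordinate centering** — latitude/longitude are centered on zero using
  the grand mean over all non-missing site-years pooled across years; a
  single fixed origin keeps coefficients comparable across years.
* **Missingness** — unsurveyed route-years are missing, never zero, and are
  skipped by every likelihood term; they are treated as missing at random
  (the monitoring design grew over the years by adding routes).

## Sampler (`sampler`)

A data-augmentation MCMC written for this model family:

1. `z` is Gibbs-sampled exactly from
   `P(z=1 | y, psi, p) = psi prod(1-p) / (psi prod(1-p) + 1-psi)` for
   all-zero histories and forced to 1 wherever a detection exists.
2. Every logit-scale intercept `u(i,t)`, `v(i,t)` and slope `a_c(i)`,
   `b1(i)` moves by random-walk Metropolis against the data-augmented
   posterior. Blocks that are conditionally independent (all species-year
   intercepts; all species within one slope column) are proposed and
   accepted elementwise in a single vectorized pass.
3. Normal means (species-level and community-level) are conjugate draws;
   the uniform-prior sds move by random-walk Metropolis.

Proposal scales adapt per element by Robbins-Monro toward 0.44 acceptance
during burn-in only and are frozen afterwards, so the post-burn-in kernel
exactly preserves detailed balance. Update order is fixed (z, u, a, v, b,
species means/sds, hyper-parameters); correctness rests on each block's
invariance, not on any particular schedule.

Numerics: the Bernoulli-logit log-likelihood is computed as
`z*eta - softplus(eta)` with overflow-safe softplus; per-state softplus
arrays are cached and updated on acceptance so each proposal costs one
fresh softplus evaluation. The masked sums and in-place accept/update
passes are JIT-compiled with numba when available, with equivalent pure
numpy fallbacks.

Initialization: `z` at the observed maxima, intercepts at jittered
empirical logits (naive occupancy/detection frequencies clipped to
[0.05, 0.95]), slopes near zero, all sds at 1.0 on the logit scale — well
inside the Uniform(0, 10) support while keeping the first burn-in sweeps in
a sensible region. A neutral fallback state is tried if the initial
posterior is non-finite.

Default protocol: 3 chains x 30,000 iterations after 20,000 burn-in,
thinned by 10 — 3000 stored draws per chain, 9000 pooled. Tests and the
acceptance script use the desk-scale protocol 3 x 4000 / 2000 / thin 2,
which the recovery experiments below show is calibrated at the default
synthetic scale.

## Diagnostics (`diagnostics`)

* **Gelman-Rubin R-hat** — classic unsplit form
  `sqrt(((n-1)/n W + B/n) / W)`; a split-chain variant is available.
  Fits with any R-hat above 1.1 (configurable) have their summaries
  withheld by the pipeline unless forced.
* **Bayesian p-value** — for each retained draw a replicate dataset is
  simulated from the model and a discrepancy is compared between observed
  and replicated per-(site, species, year) detection counts against their
  marginal expectation `psi * sum_k p_k`. Default discrepancy is the
  Freeman-Tukey distance `sum (sqrt(c) - sqrt(E))^2` (a binomial deviance is
  available); the statistic itself is a modelling choice, not uniquely
  dictated by the analysis being reproduced. Ties count toward "at least as
  extreme", so a constant discrepancy yields p = 1.

## Summaries (`summaries`)

95% credible intervals are empirical 2.5/97.5 percentiles pooled across
chains (linear interpolation). A species is classified *negative* for a
covariate when the 97.5% quantile of its coefficient is below zero,
*positive* when the 2.5% quantile is above zero, *neutral* otherwise; no
multiplicity adjustment is applied across species x covariates (a known
caveat of the interval-exclusion rule, kept for comparability).
Occupancy summaries (regional means by year, per-site surfaces) transform
each draw through the inverse logit before averaging — never the inverse
logit of an averaged linear predictor.

## Synthetic data (`synth`)

The generator runs the model forward on a synthetic landscape:

* Routes sit on a jittered grid over a centered unit square; sites inherit
  route coordinates with small along-route offsets.
* Land-cover intensities follow smooth low-order spatial trends plus
  truncated Gaussian noise, jointly renormalized with an unclassified
  background so the four modelled proportions sum to at most one. Defaults
  emulate the study region's broad pattern — soybean widespread and
  strongest centrally (site proportions spanning roughly 0-0.7, sd ~0.13),
  native forest concentrated in one corner, pasture increasing northward,
  corn patchy — giving between-site covariate variation of realistic
  magnitude. Point-level forest cover is Beta-distributed around the site
  value (concentration 25), exact in expectation.
* Community truth defaults: occupancy intercepts N(-0.6, 1.0) across
  species (mean psi ~0.35), detection intercepts N(-0.85, 0.7) (mean p
  ~0.30, most species below 0.5), year-effect sds 0.3. Named presets give a
  zero-effect truth (all slopes exactly zero), moderate mixed-sign effects,
  and a strong shared single-covariate effect.

What the generator does *not* emulate: spatial autocorrelation between
points (the analysis assumes points 1 km apart are independent), closure
violations within a site, observer effects beyond the year random effect,
and abundance-induced detection heterogeneity. Passing recovery tests
therefore validate the estimator under the model's own assumptions, not
robustness to their violation.

## Validation harness (`pipeline`)

Two independent oracles, deliberately sharing no code with the paths they
check:

* `enumerate_loglik` — brute-force sum over all 2^(S N Y) latent
  configurations; the marginal likelihood must agree to 1e-10 on every toy
  with S N Y <= 12.
* `toy_grid_posterior` — 601^2-point grid integration of the
  single-species, no-covariate posterior over (logit psi, logit p) under
  the same N(0, 10) priors; MCMC posterior means must agree within two
  Monte-Carlo standard errors.

`recovery_experiment` repeats simulate -> fit -> summarize (default: 20
replicates, 15 species, 20 routes = 120 sites, K = 5, 3 years, 3 x 4000 /
2000 / thin 2, zero-effect truth) and reports bias and empirical 95% BCI
coverage of the nine community hyper-means plus the effect-classification
fractions. Expected behaviour: coverage near 0.95; the non-neutral
classification rate at or *below* the nominal 5% because hierarchical
shrinkage toward a community mean of zero makes the interval-exclusion rule
conservative under the null.

## Design choices where the design was open

* Supplementary table layouts are mapped through a `TableSchema` descriptor
  onto one canonical long format (route, point, year, species, detection),
  decoupling the model from any particular CSV dialect.
* The sampler draws `z` (data augmentation) but the marginal likelihood is
  also implemented and used by the oracles; both routes must agree.
* Groups (e.g. raptors, ground granivores) are fitted as fully independent
  model runs.
* The acceptance script runs the zero-effect recovery at 10 replicates and
  reports the same statistics the 20-replicate test suite checks; both
  sizes give binomial errors small enough to see miscalibration of the
  magnitudes of interest.

## Known limitations

* The hierarchical slope distributions make per-species classifications
  conservative when the community sd is small; this is a property of the
  model, not a bug, but it means per-species "effects" are harder to earn
  for species with little data.
* R-hat on a handful of weakly identified hyper-sds can exceed 1.1 at the
  desk-scale protocol; the full protocol (3 x 30,000) is the configuration
  of record for real analyses.
* The Bayesian p-value with the Freeman-Tukey discrepancy detects gross
  heterogeneity misfit but is a blunt instrument. On model-true data its
  distribution is not uniform: each replicate is simulated at the same
  parameter draw it is scored against, while the observed data carry an
  extra parameter-mismatch term, so with a diffuse posterior (very small
  datasets) p-values sit left of 0.5 and can graze 0.05 without any real
  misfit. With informative desk-scale data they fall comfortably in the
  interior; interpret extreme values jointly with the data size.
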