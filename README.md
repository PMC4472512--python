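# commocc

Hierarchical multi-species, multi-season occupancy models for roadside
point-count monitoring data.

Regional bird monitoring programs survey routes of roadside points once per
breeding season and record, for every species, whether it was seen or heard
at each point. Because detection is imperfect (p < 1), a species absent from
the records may be truly absent or merely missed; raw detection rates
confound distribution with detectability. `commocc` is for analysts of such
programs who want per-species estimates of occupancy (psi) and of land-use
effects on occupancy that account for imperfect detection, across dozens of
species at once.

## The model

Routes of 30 points are partitioned into sites of k = 5 consecutive points;
the points of a site act as spatial replicates. For species *i*, site *j*,
year *t*:

```
z(j,i,t) ~ Bern(psi_jit)                        (latent presence)
logit psi_jit = u(i,t) + a1(i) lat + a2(i) long + a3(i) soy
              + a4(i) corn + a5(i) per_past + a6(i) forest

y(j,k,i,t) ~ Bern(p_jkit * z(j,i,t))            (detection at point k)
logit p_jkit = v(i,t) + b1(i) p_fors(j,k,t)
```

Intercepts are random year effects around species means, and species means
and slopes are draws from community-level normal hyper-distributions, so
sparsely detected species borrow strength from their group. The model is
fitted by a data-augmentation MCMC written for this likelihood (exact Gibbs
for z, adaptive random-walk Metropolis for the logit-scale parameters,
conjugate draws for the normal means), with Gelman-Rubin convergence
checks, a posterior-predictive Bayesian p-value, and summaries that
classify each species x covariate effect by whether its 95% credible
interval excludes zero.

See `docs/methods.md` for the full model, priors, sampler and validation
details.

## Worked example

Simulate a small community with known truth (community-mean soybean slope
-1.0, forest slope +1.0), fit it, and summarize:

```python
from commocc import (GroupData, PriorSpec, MCMCConfig, run_mcmc, diagnose,
                     summarize_effects, classify_fractions)
from commocc.synth import (default_design, simulate_landscape,
                           simulate_community, moderate_truth)

design = default_design(n_routes=10, n_years=2)       # 60 sites, 5 points each
site_cov, point_cov = simulate_landscape(design, seed=1)
bundle = simulate_community(design, site_cov, point_cov, moderate_truth(),
                            n_species=8, seed=2)
data = GroupData.from_inputs(bundle.history, site_cov, point_cov)
draws = run_mcmc(data, PriorSpec(),
                 MCMCConfig(n_chains=3, n_iter=2000, burn_in=2000, thin=2, seed=3))
report = diagnose(draws, data, seed=0)
print(f"max R-hat: {report.max_rhat:.3f}   Bayesian p-value: {report.pvalue:.2f}")
effects = summarize_effects(draws)
print(effects[effects.covariate == "soy"].round(2).to_string(index=False))
```

```
max R-hat: 1.133   Bayesian p-value: 0.08
species covariate  mean   sd  q2.5  q97.5 classification
  sp001       soy -1.18 0.86 -2.83   0.61        neutral
  sp002       soy -1.73 1.29 -4.83   0.14        neutral
  sp003       soy -0.75 1.10 -2.80   1.87        neutral
  sp004       soy -1.92 1.69 -6.28   0.40        neutral
  sp005       soy -1.20 1.03 -3.40   0.73        neutral
  sp006       soy -1.09 1.34 -3.59   1.97        neutral
  sp007       soy -1.84 1.21 -4.71  -0.01       negative
  sp008       soy -1.54 1.17 -4.41   0.29        neutral
```

The posterior means track the true per-species slopes (here between -1.5
and +0.2), every interval covers its truth, and only the strongest effect
is individually resolvable at this deliberately small problem size — with a
desk-scale run (60 sites, 2 years, a few thousand iterations) single-species
effects of ~1 on the logit scale sit near the edge of detectability, which
is exactly what the wide intervals say. The Bayesian p-value (0.08, inside
(0.05, 0.95)) raises no misfit flag; an R-hat slightly above 1.1 on a
weakly identified hyper-parameter signals that a real analysis should use
the full protocol (`MCMCConfig()`: 3 chains x 30,000 after 20,000 burn-in,
thinned by 10 — 3000 stored draws per chain, 9000 pooled).

A command-line interface mirrors the library:

```
commocc simulate --seed 1 --n-species 15 --out runs/sim
commocc prepare --detections runs/sim/detections.csv \
    --site-covariates runs/sim/site_covariates.csv \
    --point-covariates runs/sim/point_covariates.csv --min-obs 200 --out runs/prep
commocc fit --data runs/prep --seed 1 --out runs/draws.npz
commocc diagnose --draws runs/draws.npz --data runs/prep --out runs/rhat.csv
commocc summarize --draws runs/draws.npz --data runs/prep --out runs/summaries
```

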