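# occutrend

Occupancy-detection trend estimation from unstructured biological
records.

Volunteer recording schemes produce millions of *biological records* —
a species seen at a 1 km grid cell on a date — with no sampling
protocol. `occutrend` turns such presence-only records into
species-level distribution trends for a taxonomic group, accounting for
uneven recording effort, and aggregates them into multispecies
indicators. It is aimed at ecologists analysing recording-scheme data
(pollinators, moths, plants, ...) and at methodologists who want a
self-contained, testable implementation of the model family with a
matching synthetic-data generator.

## The model

For each species, sites *i*, years *t* and visits *v* (a visit is a
unique site × date combination within the taxonomic group; visits where
other group members were recorded but the focal species was not count
as non-detections):

```
State:        z_it ~ Bernoulli(ψ_it),   logit(ψ_it) = b_t + u_i
Observation:  y_itv | z_it ~ Bernoulli(z_it · p_itv)
              logit(p_itv) = a_t + δ₁·DT2_itv + δ₂·DT3_itv
```

`b_t` follows a first-order random walk with a half-Cauchy innovation
scale (smoothing adjacent years), `u_i` are exchangeable site effects,
`a_t` year effects on detection, and DT2/DT3 flag visits whose *list
length* (species recorded) is 2–3 or >3 — a proxy for recorder effort.
Fitting is by MCMC (Gibbs for the latent presences via the closed-form
conditional, adaptive Metropolis-within-Gibbs for the logistic-scale
parameters), with Gelman–Rubin Rhat flags per parameter. Posterior
draws of annual occupancy — the proportion of occupied cells among all
modelled cells — feed the downstream statistics: clipped per-species
growth rates with a credible-interval trend classification, composite
(geometric-mean) trends per species group via a sum-contrast log-linear
model, Simpson's evenness (−ln D), first-derivative "notable year"
flags, and net change in occupied cells extrapolated to a national
grid. See `docs/methods.md` for the full account.

Because recording-scheme data are typically not redistributable, the
package includes a generator that simulates records from the same
generative model — including recording biases (more visits in later
years, effort-dependent detection, presence-only output) — with ground
truth retained, so the whole pipeline is testable end to end.

## Worked example

Simulate a small community (6 focal species within a 26-species group,
80 sites, 10 years), prepare it, fit all six species and derive trends:

```sh
occutrend simulate --config sim.yaml --out records.csv --truth truth/
occutrend prepare  --records records.csv --min-records 30 --out prep/
occutrend fit      --prep prep/ --species-list SP001,SP002,SP003,SP004,SP005,SP006 \
                   --config model.yaml --out posteriors/
occutrend trends   --posteriors posteriors/ --n-cells 240000 \
                   --subsample 500 --seed 42 --out results/
```

with `sim.yaml` holding `n_species: 6`, `n_background_species: 20`,
`n_sites: 80`, `n_years: 10`, `visits_per_site_year: 2.5`, `seed: 42`
and `model.yaml` holding `n_chains: 3`, `n_iterations: 2000`,
`burn_in: 1000`, `thin: 3`, `seed: 7`. `results/trends.csv` then reads:

```
species  first_year  last_year  rate_median  rate_lower  rate_upper  classification
  SP001        2000       2009        -0.27       -2.48        2.31  no clear trend
  SP002        2000       2009         0.00       -3.83        3.93  no clear trend
  SP003        2000       2009         0.75       -1.63        3.84  no clear trend
  SP004        2000       2009        -3.58       -5.89       -1.26  decreasing
  SP005        2000       2009        -1.47       -5.79        4.44  no clear trend
  SP006        2000       2009        -3.58       -6.65        0.00  no clear trend
```

Rates are annual growth in occupancy (% per year) between each species'
first and last recorded years, with 95% credible intervals; a species
is classified "decreasing"/"increasing" only when its interval excludes
zero. Here the one species whose interval excludes zero (SP004, −3.6
%/yr) is indeed the fastest-declining species in the generator's ground
truth (−3.9 %/yr true rate; `truth/true_occupancy.csv`), and the
estimated rates of the others track their true values within the
intervals. `results/net_change.csv` summarizes the cohort:

```
n_species  n_cells_total  per_cell_median  extrapolated_median
        6         240000            -0.25             -60000.0
```

i.e. a posterior-median net loss of 0.25 species per cell, or 60,000
occupied cells if the community occupied a 240,000-cell national grid.
`results/composite.csv`, `evenness.csv` and `derivatives.csv` hold the
group indicator series with credible intervals and notable-year flags.

`occutrend run-all --config pipeline.yaml` drives all stages from one
file, and every stage writes a JSON provenance sidecar with its config
and seeds; rerunning with the same config reproduces the tables
exactly.

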