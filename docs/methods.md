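# Methods

## The problem

Volunteer recording schemes accumulate large numbers of *biological
records* — a species, a 1 km grid cell ("site") and a date — without any
sampling protocol. Recording effort varies between sites, years and
outings, so raw record counts confound change in species distributions
with change in recorder behaviour. This package estimates annual
occupancy (the proportion of occupied sites) per species from such
records, accounting for imperfect and uneven detection, and derives
multispecies indicators from the posterior.

## Occupancy-detection model

For each species separately, with sites i, years t and visits v (a visit
is a unique site x date combination within the taxonomic group):

```
State:        z_it ~ Bernoulli(psi_it),   logit(psi_it) = b_t + u_i
Observation:  y_itv | z_it ~ Bernoulli(z_it * p_itv)
              logit(p_itv) = a_t + delta1*DT2_itv + delta2*DT3_itv
```

Non-detections are inferred: a visit on which other species of the group
were recorded but the focal species was not is a non-detection. The
list length of a visit (number of species recorded) proxies effort;
DT2/DT3 indicate list-length categories 2 (2–3 species) and 3 (>3
species) against the single-species baseline. The model assumes no
false presences: any detection forces z_it = 1.

Priors:

* `b_t` — first-order random walk, `b_t | b_{t-1} ~ N(b_{t-1},
  sigma_rw^2)`, `b_1 ~ N(0, 10^2)`, with `sigma_rw ~ half-Cauchy(1)`.
  The walk shares information between adjacent years and smooths the
  annual occupancy estimates. The half-Cauchy scale (`rw_scale`) is
  configurable; 1 is a weakly-informative default on the logit scale.
* `u_i ~ N(0, sigma_u^2)`, `sigma_u ~ half-Cauchy(1)` — exchangeable
  site effects (sites are opaque labels; no spatial structure).
* `a_t ~ N(mu_a, sigma_a^2)`, `mu_a ~ N(0, 10^2)`, `sigma_a ~
  half-Cauchy(1)` — exchangeable year effects on detection. A location
  `mu_a` is required: `a_t` carries the detection intercept, so a
  zero-centred prior would pin baseline detectability at 0.5.
* `delta1, delta2 ~ N(0, 10^2)` — vague.

### Sampler

The MCMC engine is written for this model:

* **Latent presences** are updated by exact Gibbs steps. For a site-year
  with no detection, `P(z=1 | data) = psi*q / (psi*q + 1 - psi)` with
  `q = prod_v (1 - p_v)`; computed on the logit scale
  (`logit(psi) + log q`) for stability. Site-years with a detection are
  set to 1. Site-years never visited draw from `psi` (q = 1), which is
  what makes annual occupancy a proportion of *all* modelled sites.
* **Logistic-scale parameters** (`b`, `u`, `a`, `delta1`, `delta2`) use
  Metropolis-within-Gibbs with Gaussian random-walk proposals.
  Conditional independence is exploited for vectorization: all `u_i`
  update in parallel, all `a_t` in parallel, and `b_t` in an even/odd
  checkerboard (the random walk couples only adjacent years). Proposal
  scales adapt toward 44% acceptance by Robbins–Monro during burn-in
  only and are frozen afterwards, so retained draws come from a valid
  Markov chain.
* **Variance hyperparameters** use the inverse-gamma scale-mixture
  representation of the half-Cauchy, giving conjugate Gibbs updates;
  `mu_a` is a conjugate normal draw.

Defaults mirror standard practice for this model family: 3 chains x
20,000 iterations, burn-in 10,000, thinning 3. Tests and the acceptance
study run reduced settings (3 chains x 2,000 iterations, burn-in 1,000,
thinning 3), which the adaptive sampler mixes well at for the problem
sizes used; the retained-draw count per chain is always
`(n_iterations - burn_in) / thin`.

`z` is initialized to 1 at any site where the species was ever detected
(any year), else Bernoulli(0.5) — faster mixing, common practice for
this family. Chains start from dispersed random points.

Convergence is summarized by the classic Gelman–Rubin Rhat per monitored
parameter (annual occupancy, `b_t`, `a_t`, scalars). Parameters with
Rhat above 1.1 are flagged with a warning but their draws are retained,
since occasional unconverged nuisance parameters do not directionally
bias the high-level summaries; the flags are written next to the
posterior so users can judge.

Degenerate histories (no detections; detection on every visit; a single
modelled year) are refused with explicit errors rather than silently
producing an improper posterior.

## Synthetic-records generator

The generator draws from exactly the generative model above — species
with heterogeneous baseline occupancy (`logit` spread `species_sd`),
random-walk year effects, shared site effects, year-varying
detectability and list-length detection offsets — plus the recording
process: a Poisson visit schedule per site-year whose rate grows
linearly across years (`visit_growth`, default 2x) to emulate the
temporal bias of volunteer data, and presence-only output (only
detections are emitted; outings recording nothing leave no trace).

Two design points deserve note:

* **List-length self-consistency.** The category of a visit is derived
  from the detections actually emitted, not pre-assigned, because that
  is how the covariate arises in real data. Detection probabilities
  depend on the category, and the category on the detections; with one
  uniform draw per (visit, species) the map from category to realized
  list length is monotone whenever the offsets are non-negative, so the
  iteration reaches a fixed point (at most three steps over the three
  categories). The preparation stage reconstructs the generator's visit
  categories exactly — this round trip is tested.
* **Background species.** Real scheme groups contain one-to-two hundred
  species, so virtually every recorded outing yields at least one
  record. If a generator simulates only a handful of species, dropping
  empty outings makes the very *existence* of a visit informative about
  the focal species — a selection artifact absent from real data, which
  we measured to depress interval coverage badly in small communities.
  `n_background_species` (default 40) therefore simulates the
  unmodelled remainder of the taxonomic group with the same generative
  model; background species appear in records (as "BG..." ids) and in
  list lengths, exactly like the non-focal species of a real scheme.
  Setting it to 0 exposes the artifact for study.

Default magnitudes are chosen as plausible for a recording-scheme
dataset rather than calibrated to any particular scheme (the real
visit-frequency distribution is not characterized): baseline occupancy
0.3 with 0.7 logit spread between species, site sd 1.0, random-walk
innovation sd 0.15/yr, detection ~0.35 on single-species lists with
offsets +0.8 (category 2) and +1.6 (category 3), 2 visits per site-year
growing to 4. Dates are arbitrary unique days within a year; the model
has no within-year structure. There is no spatial autocorrelation, no
observer identity, and no misidentification process; passing recovery
tests therefore show correctness of the inference under the model's own
assumptions, not robustness to violations of them.

## Preparation

Filters are applied in a fixed, documented order: (1) clip to the year
window; (2) drop sites with fewer than 2 distinct years of remaining
data; (3) apply the optional species exclusion list, then drop species
with fewer than 50 remaining records (exactly 50 is retained). The
order is a package decision: site quality is judged within the study
window, and species totals within retained sites. Duplicate rows are
collapsed on ingest (a record is by definition unique) and counted. The
filter report reconciles every removal exactly and is asserted to.

## Downstream statistics

All statistics operate on a seeded subsample of posterior occupancy
draws (default 1000 per species) so uncertainty propagates through
every derived quantity; credible intervals are equal-tailed quantiles
(2.5/97.5 and 10/90).

* **Clipping.** Occupancy estimates before a species' first record and
  after its last are extrapolations of the smoothing prior and are
  dropped before trend estimation. Species left with fewer than 2 years
  are excluded from trends with a warning.
* **Growth rate.** Per draw, the compound annual rate
  `100*((occ_last/occ_first)^(1/years) - 1)`; an arithmetic variant is
  available behind a switch for sensitivity checks. Classification:
  "decreasing" iff the 95% CI is entirely below zero, "increasing" iff
  entirely above, else "no clear trend".
* **Composite trend.** Per draw, log occupancy is regressed on year and
  species as categorical effects with sum-to-zero contrasts; the year
  effects, back-transformed, are the composite. On complete tables this
  *equals* the per-year geometric mean (tested to floating precision);
  with clipped species the unbalanced least-squares fit adjusts for
  missing species-years, which is the reason to use a model at all.
* **Evenness.** Simpson's evenness in the `-ln D` form on normalized
  occupancy shares: `D = sum_i (occ_i / sum_j occ_j)^2`. Equals `ln S`
  for equal shares and tends to 0 under single-species dominance;
  declines signal concentration of occupancy in few widespread species.
  Computed on the full modelled span so species share a year axis.
* **Derivatives and notable years.** Per draw, differences between
  adjacent years; a year is flagged a notable decrease (increase) when
  the 95% CI of the difference lies below (above) zero. Bounds within
  1e-12 of zero do not flag (floating roundoff on degenerate constant
  series). 80% intervals are reported alongside for plotting.
* **Net change.** Per draw, the sum over species of (last − first)
  clipped occupancy — the net change in species per cell — scaled by
  the total cell count (default 240,000) for a national figure. Species
  endpoints are their clipped first/last years, not the global window.
* **Epsilon floor.** Occupancy draws are floored at `1/(2*n_sites)`
  before logs and ratios: a z-based occupancy can be exactly zero in a
  draw, and the floor sits below the resolution of the site grid.

## Problem sizes

The recovery study used by the tests and the acceptance script fits 20
focal species in a 60-species community over 100 sites x 10 years with
~3 visits/site/year, at 3 chains x 2,000 iterations — chosen as the
smallest configuration at which all structural features (list-length
mix, temporal visit bias, random-walk smoothing) are active while a
complete study runs in minutes. Coverage of the 95% intervals is
assessed against a threshold of 0.85, i.e. two binomial standard errors
below the nominal 0.90 at 200 species-years, since hierarchical
shrinkage can legitimately trade a little coverage for variance.

## Known limitations

* Exchangeable detection year effects: detectability trends that are
  correlated with occupancy trends are only partly separable.
* The sampler is single-machine and per-species; hundreds of species at
  full MCMC settings imply hours of compute (fits are embarrassingly
  parallel and order-independent).
* No false-positive process; misidentified records bias occupancy
  upward with no diagnostic.
* Evenness requires a common year axis and therefore uses unclipped
  series; for species whose records span a sub-window, early/late
  evenness leans on the smoothing prior.
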