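# Methods

## The problem

Seabird bycatch in pelagic longline fisheries is a rare event (well under 1%
of sets catch a bird) with strong spatial structure: bycatch probability
clusters along shelf waters, the cluster moves between years, and the
movement tracks basin-scale climate variation. Observer programs record
bycatch on a small fraction of sets; fleet-wide logbooks record effort but
not bycatch. The analysis chain implemented here (i) fits a Bayesian
spatiotemporal hurdle model to observer-style data, (ii) extrapolates
expected bycatch to the full logbook fleet with uncertainty, (iii) extracts
annual bycatch hotspots and tests their lagged coupling to a climate index,
and (iv) simulates fleet-behavior changes (removing or relocating effort) to
rank mitigation options. Because real observer/logbook records are
confidential, the package ships a synthetic-data generator that reproduces
the statistical structure the models assume, and every claim the test suite
makes is about recovery of known synthetic truth.

## Hurdle model

For set *i* with bycatch count *y&#8334;*:

* occurrence: `z_i ~ Bernoulli(p_i)`,
  `logit(p_i) = β₀ + Σ f(c_i) + Σ s(x_i) + u_{v(i)} + ξ(s_i)`;
* positive count: `y_i | z_i=1 ~ ZTPoisson(λ_i)`,
  `log λ_i = α₀ + s(hooks_i) + f(haul time_i)`.

`f` are categorical effects (year, season, target species, set time) coded
with one column per level and a soft sum-to-zero constraint (a quadratic
penalty with precision 10⁴ on the level sum) so the latent model stays
Gaussian; `s` are first-order random-walk (RW1) smooths on m = 20 equal-width
half-open bins of a continuous covariate (boundary values join the lower
bin), with the same soft constraint resolving the RW1 rank deficiency;
`u_v ~ N(0, τ_v⁻¹)` are i.i.d. vessel effects; `ξ` is a Matérn spatial field,
either constant over years or with one independent realization per year
given shared hyperparameters. The positive model's log link is placed on the
**untruncated** Poisson rate λ; truncation enters only through the
likelihood `y log λ − λ − log(1 − e^{−λ}) − log y!`. The expected bycatch of
a set is the hurdle composition `E[y] = p · λ/(1 − e^{−λ})`.

## Spatial field: SPDE and the coastline barrier

The Matérn field (smoothness ν = 1, i.e. SPDE order α = 2 in 2-D — the
standard default) is represented as a GMRF on a triangular mesh via P1 finite
elements. With κ = √8/range, lumped mass C and stiffness G:

    Q = τ² (κ²C + G) C⁻¹ (κ²C + G),   τ² = 1/(4π κ² σ²).

The barrier variant assigns each triangle a range — the open-water range in
water, a fixed fraction (default 0.1) of it inside coastline polygons — and
assembles

    Q = A M⁻¹ A,  A = C + Σ_d (r_d²/8) G_d,  M = (π/2) σ² Σ_d r_d² C_d,

which reduces *exactly* to the stationary form when no triangle is flagged.
Correlation then cannot travel across land: the test suite verifies that
across-barrier correlation at matched distance is strictly below open-water
correlation and decreases monotonically in the barrier fraction.

Meshes are built from a regular fine vertex grid over the (planar) study
boundary plus a coarser vertex ring extending the mesh outward, Delaunay
triangulated, with barrier/extension status assigned per triangle by centroid
membership. The grid spacing is `max_edge_inner/√2`, so every interior edge
is bounded by `max_edge_inner`. The extension ring pushes the inflated
boundary variance of SPDE fields outside the region of interest; its default
width is of the order of the field's prior median range. The barrier is
represented purely through triangle flags (not constrained edges): the
barrier precision only consumes flags, and flag resolution is controlled by
the mesh size. Geographic coordinates are projected to kilometres by
equirectangular scaling about the domain mid-latitude; all ranges and the
50-mile redistribution rule live in that metric.

## Inference: Laplace approximation over a hyperparameter grid

Both sub-models are latent Gaussian models fitted by:

1. **Inner step** — Newton optimization of the latent joint posterior to its
   mode (convergence at max |gradient| < 10⁻⁶, at most 50 iterations, with
   backtracking line search; failures raise, never pass silently), then a
   Gaussian approximation with precision `Q₀ + Bᵀ W B` at the mode. A linear
   predictor beyond ±30 is flagged as separation; a zero-truncated rate
   driven to the λ→0 boundary (all counts equal to 1) raises a warning.
2. **Outer step** — the hyperparameters θ (log field range, log field σ, log
   RW1 precision, log vessel precision — only those the model contains) are
   explored on a small tensor grid centred at a Nelder–Mead optimum of
   hyperprior × Laplace marginal likelihood; grid weights are the normalized
   posterior masses. Sparse LDLᵀ factorizations (SuperLU in symmetric mode)
   provide solves, log-determinants and posterior draws; a failed
   factorization is retried once with 10⁻⁸ diagonal jitter, logged.

This mimics the nested-Laplace machinery of the standard R implementation at
desk scale; the simple Gaussian approximation (no skewness correction) was
validated against a long random-walk-Metropolis chain on a small model
(posterior means within 0.05 posterior sd at n = 600; at much smaller n the
mode-vs-mean skew of the logistic posterior becomes visible, which is
expected of any Laplace-type method).

**Priors.** Fixed effects N(0, 31.6²). Field: penalized-complexity-style
priors, P(range < r₀) = 0.5 with r₀ = half the domain diameter by default,
and P(σ > 1) = 0.1. RW1 and vessel precisions: PC priors with
P(sd > 1) = 0.1. All settings are config-exposed.

**DIC / WAIC.** From seeded posterior draws of the linear predictor:
DIC = 2·D̄ − D(η̄) (i.e. p_D = D̄ − D at the posterior-mean predictor);
WAIC = −2(LPPD − p_WAIC) with pointwise log-predictive density and the
variance-based parameter count. Both are reported per component (occurrence
and positive), never summed, matching the two-ladder presentation of the
model-comparison tables. A dense 1-D quadrature oracle on an intercept-only
model reproduces the DIC within 0.5.

**Stepwise selection.** Forward from intercept-only, adding at each step the
candidate with the largest DIC reduction, stopping when the best reduction is
below 5; the spatial term is offered only after the covariates settle. The
trace (terms, DIC_z, DIC_y, WAIC_z, WAIC_y per step) is written as a CSV in
the model-ladder layout.

## Fleet extrapolation

1000 (configurable) joint draws are taken from the grid-mixture Gaussian
approximation; each logbook set gets a per-draw expected bycatch
`p·λ/(1−e^{−λ})` at its covariates and location. Group totals are summed
**within** draw and then summarized across draws — so a group CV reflects the
correlated posterior uncertainty of its members, and zone totals add up to
the overall total exactly, draw by draw. Sets outside the mesh are excluded
and counted; vessels unseen in training receive effects drawn per draw from
the fitted vessel population distribution (both logged).

## Hotspots and climate

The hotspot of a year is the in-domain mesh node maximizing that year's
posterior-mean spatial effect (ties → lowest node index; a config switch
ranks by predicted probability instead — same argmax, different reported
value). Years without a positive training set have no hotspot. Hotspot
latitude is Pearson-correlated with the climate index at lags 0..K with
pairwise deletion of missing years; a lag needs ≥8 overlapping pairs, and
significance uses the two-sided large-sample band |r| > 1.96/√n. The
small-sample inflation of that band is real (the null false-positive rate at
26 years runs near 6–7%, not 5%) and is asserted as such in the tests.

## Mitigation scenarios

Hotspot *areas* are the top-decile cells of the hindcast per-set expected
bycatch surface on a 1° grid (cell value = mean predicted per-set bycatch of
the sets it contains). Six scenarios remove or redistribute up to 5,000 sets
(500 in the reduced test profile): removal from hotspot cells, from the
summer–spring season, or from hotspot∩summer-through-winter; redistribution
from hotspots to uniformly sampled water cells at least 50 miles from every
hotspot cell, from summer-through-winter to spring, or both combined. Each
of the 1,000 (100 reduced) repetitions resamples both the affected sets and
one posterior draw, scoring % change in predicted bycatch and in per-species
catch against the same-draw baseline. Repetition streams are keyed by
(seed, source filter, repetition), so scenarios sharing a source filter act
on identical set samples — removal vs redistribution comparisons are paired.
Repetitions with no eligible destination are aborted and counted, never
silently skipped. Fish catch at a relocated set comes from a deliberately
simple stand-in predictor: the mean catch of the k = 25 nearest logbook sets
with the same season and target species around the destination.

## Synthetic data generator

The generator emulates the features the analysis depends on, with these
study conditions as defaults:

* **Effort concentration** — six stylized zones; weights 0.35/0.18/0.14/
  0.12/0.07/0.14 so five zones hold ~86% of effort, matching the published
  zone tallies; seasonal shares 0.20/0.27/0.31/0.22 (winter/spring/summer/
  fall); ~60 vessels with zone affinity.
* **Rarity** — the Bernoulli intercept is solved (1-D root find) so the mean
  occurrence probability equals the target positive-set share, 0.5% by
  default.
* **Covariate effects** — negative water-temperature slope on logit(p)
  (−0.5 per standardized °C, calibrated so that adding temperature to an
  intercept-only occurrence model at ~20k sets improves the deviance by
  ~75, the order reported for the real observer data), seasonal offsets with
  spring lowest, day setting above night setting, positive hooks effect and
  day haul-back effect on the positive count. Temperature itself has a
  seasonal cycle plus a steep latitudinal gradient (0.8 °C/deg), leaving
  genuine within-season contrast between temperature and season.
* **Hotspot** — a Gaussian bump (amplitude 2.5 on the logit scale, width
  160 km) whose centre latitude is displaced by slope × climate index lagged
  two years; the climate index is AR(1) with unit marginal variance.
* **Catch** — per-species log-linear Poisson catch with tuna concentrated
  along a shelf-break line, so mitigation scenarios face the real trade-off
  (hotspot cells overlap the best tuna grounds).

What the generator does **not** emulate: observer vessel-rotation sampling
(coverage is uniform), species identity of caught birds, bathymetry, real
shorelines, or real climate indices. Tests passing on these data show that
the machinery recovers the structure it models; they do not validate the
ecological assumptions on real data.

## Validation studies and problem sizes

The replicated studies (all seeded, all regenerating data from scratch) use
sizes chosen to give stable rates on a single CPU:

* recovery — 100 datasets × 5,000 sets at 0.5% positives; 95% intervals
  cover the true fixed effects ≥90% of the time and the temperature sign is
  recovered ≥95% of the time; the vessel sd is set to zero here to isolate
  fixed-effect behaviour.
* selection — 100 datasets × 8,000 sets with one active covariate
  (temperature slope −1.0, its "only active covariate" scenario) and three
  4-level noise factors.
* lag recovery — 100 datasets × 12,000 sets over 24 years in the three
  shelf zones, positive share 2% (hotspot estimation needs a handful of
  positive sets per year), slope 2.5°/unit so the climate-driven latitude sd
  clearly exceeds hotspot-extraction noise, and a white-noise index so that
  lag-1 leakage from index autocorrelation (a genuine correlation, not an
  artifact) does not contaminate the false-positive measurement.
* mitigation ordering — one 15,000-set fleet scored by the known truth, 100
  paired repetitions of 500 moved sets.
* determinism — the full reduced pipeline (8,000 sets, 8 years, coarse
  meshes, 80 draws, 20 scenario repetitions) run twice; every artifact must
  be byte-identical.

## Numerical choices and degenerate inputs

* Half-open bins [a, b) with the top value joining the last bin; prediction
  values outside the training range clip to edge bins.
* Exact zero-truncated Poisson simulation by inverse transform (uniform on
  (e^{−λ}, 1]), no rejection loops.
* Likelihood Hessian entries floored at 10⁻¹⁰; λ overflow-clipped at
  e⁵⁰ before use.
* Constant hindcast surface → empty hotspot mask with a warning; a scenario
  repetition with no eligible destination aborts and is counted; a zero
  baseline total reports 0% change.
* Argmax ties (hotspot) and equal DIC candidates resolve to the first/lowest
  index, deterministically.
* A single master seed fans out to stage seeds through `SeedSequence`;
  every stage's artifacts regenerate bit-identically.

## Known limitations

* The Laplace approximation has no nested correction; hyperparameter grids
  are coarse (1–5 points per dimension depending on profile). Posterior
  means of strongly skewed low-count posteriors are mode-biased at very
  small n.
* The soft sum-to-zero constraint is a penalty, not an exact conditioning;
  level sums are pinned to ~10⁻² rather than 0.
* Meshes are structured-grid Delaunay triangulations; barrier geometry is
  honoured through triangle flags, not constrained edges.
* The catch predictor for relocated sets is a kNN stand-in, adequate for
  ranking scenarios on synthetic data but not a fishery production model.
* CVs are computed across posterior draws only; observer sampling error is
  not propagated.
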