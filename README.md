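# bycatch

Bayesian spatiotemporal hurdle modelling of seabird bycatch in pelagic
longline fisheries: barrier-aware Matérn spatial fields, fleet-wide bycatch
extrapolation, annual hotspot tracking with lagged climate cross-correlation,
and fleet-effort mitigation simulation.

## Who this is for

Fisheries and quantitative-ecology analysts working with observer-program
bycatch records: rare-event counts (≪1% of sets positive) observed on a
small sample of a fleet whose full effort is known only from logbooks, with
strong spatial clustering interrupted by coastlines. The package provides the
complete analysis chain on synthetic data with known truth — real observer
and logbook records are confidential — so every stage is testable end to end.

## The model

Bycatch per longline set follows a two-part **hurdle**: occurrence is
Bernoulli with a logit link, and the positive count is zero-truncated
Poisson with a log link on the untruncated rate,

    logit(p) = β₀ + Σ f(c) + Σ s(x) + u_vessel + ξ(s)
    log λ    = α₀ + s(hooks) + f(haul time)
    E[bycatch per set] = p · λ / (1 − e^{−λ})

with sum-to-zero categorical effects `f`, RW1 smooths `s` on binned
continuous covariates, i.i.d. vessel effects `u`, and a Matérn (ν = 1)
spatial field `ξ` — constant or with an independent realization per year —
represented as a GMRF through the SPDE finite-element construction
(`Q = τ²(κ²C + G)C⁻¹(κ²C + G)`, κ = √8/range). A **barrier** variant shrinks
the field's range inside coastline polygons so correlation cannot cross
land. Inference is a Laplace approximation at the latent mode over a coarse
hyperparameter grid; model choice is forward stepwise selection under a
Δ≥5 DIC rule with WAIC reported alongside; fleet totals, hotspot tracks,
lagged climate cross-correlations and six effort removal/redistribution
scenarios are computed from seeded posterior draws. `docs/methods.md` has
the full account.

## Worked example

```bash
cd /path/to/repo
python analysis/01_simulate.py      # synthetic fleet + observer data
python analysis/02_fit_select.py    # mesh + stepwise DIC selection
python analysis/03_predict_fleet.py # fleet-wide bycatch extrapolation
python analysis/04_hotspot_climate.py
python analysis/05_mitigation.py
```

`01_simulate.py` generates a 40,000-set logbook fleet over 16 years and a
12,000-set observer subsample in the rare-event regime:

```
fleet sets:        40,000
observer sets:     12,000 (30% coverage)
positive sets:     53 (0.44% — rare-event regime)
birds caught:      92
```

`02_fit_select.py` grows both sub-models from intercept-only; each trace row
is one accepted step (Δ≥5 DIC rule, spatial field offered last):

```
model                           probability_terms positive_terms   DIC_z   DIC_y
   M0                                   intercept      intercept  682.51  131.79
   M1                      intercept + water_temp      intercept  661.43  131.79
   M2           intercept + water_temp + set_time      intercept  653.42  131.79
   M3 intercept + water_temp + set_time + spatial      intercept  642.64  131.79
```

(the negative water-temperature effect and the spatial field carry the most
information; at this reduced scale the ~25-positive-set positive sub-model
keeps only its intercept). `03_predict_fleet.py` extrapolates to all 40,000
logbook sets — totals are mean/sd/CV across 300 joint posterior draws,
summed within draw first:

```
fleet total expected bycatch: 359.7 birds (CV 17.7%) over 40,000 sets
group  n_sets    mean     sd    cv
  MAB    7215  123.16  26.97  0.22
  SAB    4787   56.84  15.09  0.27
  GOM   13962   56.12  17.88  0.32
  ...
```

— the shelf zone holding 18% of the effort carries ~34% of the predicted
bycatch, the signature of a bycatch hotspot decoupled from effort.
`04_hotspot_climate.py` extracts each year's hotspot from the
year-replicated field fitted to the three shelf zones (years with no
positive set are missing) and cross-correlates its latitude with the climate
index; `05_mitigation.py` ranks the six scenarios, e.g.:

```
scenario             metric  mean  lo95  hi95
       1 pct_bycatch_change -3.91 -5.57 -2.41
       1   pct_catch_change -1.23 -1.26 -1.20
       4 pct_bycatch_change -2.32 -4.21 -0.53
       4   pct_catch_change  0.03 -0.00  0.06
```

removing 500 hotspot sets (scenario 1) cuts predicted bycatch ~3.9% at a
1.2% catch cost; relocating the same sets ≥50 miles away (scenario 4) keeps
most of the bycatch reduction at essentially no catch cost. Numbers above
are from `master_seed=1`; a rerun with the same seed reproduces every
artifact bit-identically.

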