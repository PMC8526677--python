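"""Posterior prediction/aggregation and hotspot/climate cross-correlation."""

import numpy as np
import pandas as pd
import pytest

from bycatch.hotspot import annual_hotspot, ccf_lagged, hotspot_track, \
    zero_bycatch_years
from bycatch.hurdle import ModelSpec, _zt_mean, build_design, fit_bernoulli, \
    fit_hurdle
from bycatch.mesh import build_mesh
from bycatch.predict import (SetExpectations, aggregate,
                             expected_bycatch_per_set, per_set_summary,
                             posterior_draws, single_draw_scorer)
from bycatch.synth import ClimateSeries


@pytest.fixture(scope="module")
def small_fit(observer_data):
    obs = observer_data.head(6000)
    return obs, fit_hurdle(obs, ModelSpec(probability_terms=["season"],
                                          positive_terms=["haul_time"]),
                           seed=2)


class TestPosteriorDraws:
    def test_reproducible(self, small_fit):
        _, fit = small_fit
        a = posterior_draws(fit, 50, seed=9)
        b = posterior_draws(fit, 50, seed=9)
        np.testing.assert_array_equal(a.xz, b.xz)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_mean_matches_mixture_mean(self, small_fit):
        _, fit = small_fit
        d = posterior_draws(fit, 4000, seed=1)
        target = fit.z.posterior_mean_latent()
        sd = fit.z.posterior_latent_sd(np.arange(fit.z.design.n_latent))
        assert np.all(np.abs(d.xz.mean(axis=0) - target)
                      < 5 * sd / np.sqrt(4000) + 1e-3)

    def test_single_grid_point_draws_are_gaussian(self, small_fit):
        from scipy.stats import normaltest
        _, fit = small_fit
        assert len(fit.z.grid) == 1
        d = posterior_draws(fit, 2000, seed=3)
        p = normaltest(d.xz[:, 0]).pvalue
        assert p > 0.01

    def test_draw_count_validated(self, small_fit):
        _, fit = small_fit
        with pytest.raises(ValueError):
            posterior_draws(fit, 0, seed=1)


class TestExpectedBycatch:
    def test_closed_form_composition(self, small_fit):
        """p = 0.5 and lambda = ln 2 give E[y] = 0.5 * ln2/(1-0.5) = ln 2."""
        obs, fit = small_fit
        draws = posterior_draws(fit, 3, seed=4)
        draws.xz[:] = 0.0                      # logit(p) = 0 => p = 1/2
        draws.xy[:] = 0.0
        # set every latent weight via intercept only: eta_y = log(ln 2)
        draws.xz[:, 0] = 0.0
        draws.xy[:, 0] = np.log(np.log(2.0))
        # zero out non-intercept columns by zeroing their latent values
        sets = obs.head(4)
        e = expected_bycatch_per_set(draws, sets)
        hl = fit.y.design.slices["haul_time"]
        assert hl.stop - hl.start == 2          # haul_time cols zeroed above
        np.testing.assert_allclose(e.values, np.log(2.0), atol=1e-10)

    def test_small_rate_limit_tends_to_p(self, small_fit):
        obs, fit = small_fit
        draws = posterior_draws(fit, 2, seed=5)
        draws.xz[:] = 0.0
        draws.xy[:] = 0.0
        draws.xy[:, 0] = -14.0                 # lambda -> 0+, E -> p * 1
        e = expected_bycatch_per_set(draws, obs.head(3))
        np.testing.assert_allclose(e.values, 0.5, atol=1e-5)

    def test_zero_probability_gives_zero(self):
        assert 0.0 * _zt_mean(np.array([0.7])) == pytest.approx(0.0)

    def test_unseen_vessel_uses_population_distribution(self, observer_data):
        obs = observer_data.head(6000)
        fit = fit_hurdle(obs, ModelSpec(probability_terms=["vessel"],
                                        positive_terms=[]),
                         seed=3, optimize_hypers=False, grid_levels=1)
        draws = posterior_draws(fit, 20, seed=6)
        new = obs.head(10).copy()
        new["vessel_id"] = "V_UNSEEN"
        e = expected_bycatch_per_set(draws, new)
        assert np.isfinite(e.values).all()
        assert e.valid.all()


class TestAggregate:
    def _expect(self, values, sets):
        return SetExpectations(values=np.asarray(values, dtype=float),
                               valid=np.ones(len(sets), dtype=bool),
                               sets=sets)

    def test_hand_computed_three_draws_two_sets(self):
        sets = pd.DataFrame({"set_id": ["a", "b"], "zone": ["Z1", "Z2"]})
        vals = [[1.0, 2.0], [2.0, 2.0], [3.0, 2.0]]   # totals: 3, 4, 5
        tab = aggregate(self._expect(vals, sets))
        assert tab.loc[0, "mean"] == pytest.approx(4.0)
        assert tab.loc[0, "sd"] == pytest.approx(1.0)
        assert tab.loc[0, "cv"] == pytest.approx(0.25)

    def test_zone_totals_sum_to_overall_exactly(self, rng):
        sets = pd.DataFrame({"set_id": [f"s{i}" for i in range(40)],
                             "zone": rng.choice(["A", "B", "C"], 40)})
        vals = rng.uniform(size=(7, 40))
        e = self._expect(vals, sets)
        zones = aggregate(e, by="zone")
        total = aggregate(e)
        # additivity holds draw-wise, hence for the means
        assert zones["mean"].sum() == pytest.approx(total.loc[0, "mean"])
        assert zones["n_sets"].sum() == 40

    def test_constant_draws_give_zero_cv(self):
        sets = pd.DataFrame({"set_id": ["a", "b"]})
        tab = aggregate(self._expect([[1.0, 2.0]] * 4, sets))
        assert tab.loc[0, "cv"] == pytest.approx(0.0)

    def test_missing_group_column(self):
        sets = pd.DataFrame({"set_id": ["a"]})
        with pytest.raises(KeyError):
            aggregate(self._expect([[1.0]], sets), by="zone")

    def test_per_set_summary_shape(self, small_fit):
        obs, fit = small_fit
        draws = posterior_draws(fit, 25, seed=7)
        e = expected_bycatch_per_set(draws, obs.head(50))
        tab = per_set_summary(e)
        assert len(tab) == 50
        assert (tab["mean"] >= 0).all()

    def test_scorer_matches_matrix_route(self, small_fit):
        obs, fit = small_fit
        draws = posterior_draws(fit, 5, seed=8)
        sets = obs.head(30)
        e = expected_bycatch_per_set(draws, sets)
        sc = single_draw_scorer(draws)
        np.testing.assert_allclose(sc(sets, 2), e.values[2], rtol=1e-10)


class TestPosteriorPredictiveCalibration:
    def test_observed_total_inside_central_interval(self, domain):
        """On well-specified data the observed bycatch total falls in the
        central 95% posterior-predictive interval in most replicates."""
        from bycatch.synth import (TruthParams, gen_fleet, gen_observer_data,
                                   zero_field_sampler, sample_ztpoisson)
        truth = TruthParams(vessel_sd=0.0, field_amplitude=0.0)
        n_reps, hits = 25, 0
        for rep in range(n_reps):
            s = 9000 + rep
            fleet = gen_fleet(domain, truth, 4000, range(2004, 2010), seed=s)
            obs = gen_observer_data(fleet, truth, zero_field_sampler, 1.0,
                                    seed=s + 1)
            fit = fit_hurdle(obs, ModelSpec(probability_terms=["season"],
                                            positive_terms=[]), seed=s)
            draws = posterior_draws(fit, 250, seed=s + 2)
            e_z = (fit.z.design.B @ draws.xz.T).T
            e_y = (fit.y.design.design_for(obs) @ draws.xy.T).T
            rng = np.random.default_rng(s + 3)
            p = 1 / (1 + np.exp(-e_z))
            lam = np.exp(e_y)
            z = rng.uniform(size=p.shape) < p
            counts = np.zeros_like(p)
            counts[z] = sample_ztpoisson(lam[z], rng)
            totals = counts.sum(axis=1)
            lo, hi = np.quantile(totals, [0.025, 0.975])
            observed = obs["bycatch"].sum()
            hits += int(lo <= observed <= hi)
        assert hits >= 0.8 * n_reps


@pytest.fixture(scope="module")
def replicated_fit(domain):
    from bycatch.synth import (TruthParams, gen_climate_series, gen_fleet,
                               gen_observer_data, make_bump_field_sampler)
    truth = TruthParams(base_positive_fraction=0.03, vessel_sd=0.0,
                        field_amplitude=3.0, climate_slope=2.0)
    clim = gen_climate_series(range(2002, 2012), seed=4)
    fleet = gen_fleet(domain, truth, 6000, range(2004, 2010), seed=5)
    obs = gen_observer_data(fleet, truth,
                            make_bump_field_sampler(domain, truth, clim),
                            1.0, seed=6)
    mesh = build_mesh(domain, 250.0, 500.0, extension_km=250.0)
    dz, _ = build_design(obs, ModelSpec(probability_terms=["spatial_t"]),
                         mesh=mesh, domain=domain)
    fit = fit_bernoulli(dz, optimize_hypers=False, grid_levels=1)
    return obs, fit, mesh, domain


class TestHotspot:
    def test_planted_bump_recovered(self, replicated_fit):
        obs, fit, mesh, dom = replicated_fit
        term = fit.design.terms[1]
        k = mesh.n_nodes
        x = fit.grid[0].x_mode.copy()
        # plant a bump at a chosen in-domain node for the first year
        target = int(np.flatnonzero(mesh.node_in_domain)[7])
        x[:] = 0.0
        x[fit.design.slices["spatial_t"]][0 * k + target] = 5.0
        fit.grid[0].x_mode = x
        y0 = term.years[0]
        lon, lat, val = annual_hotspot(fit, mesh, dom, y0)
        ex, ey = dom.from_planar(*mesh.nodes[target])
        assert (lon, lat) == (pytest.approx(ex), pytest.approx(ey))
        assert val == pytest.approx(5.0)

    def test_tie_breaks_to_lowest_node(self, replicated_fit):
        obs, fit, mesh, dom = replicated_fit
        k = mesh.n_nodes
        x = np.zeros_like(fit.grid[0].x_mode)
        nodes = np.flatnonzero(mesh.node_in_domain)[[3, 11]]
        sl = fit.design.slices["spatial_t"]
        x[sl.start + nodes[0]] = 2.0
        x[sl.start + nodes[1]] = 2.0
        fit.grid[0].x_mode = x
        y0 = fit.design.terms[1].years[0]
        lon1 = annual_hotspot(fit, mesh, dom, y0)
        lon2 = annual_hotspot(fit, mesh, dom, y0)
        assert lon1 == lon2
        ex, _ = dom.from_planar(*mesh.nodes[nodes[0]])
        assert lon1[0] == pytest.approx(ex)

    def test_constant_shift_invariance(self, replicated_fit):
        obs, fit, mesh, dom = replicated_fit
        y0 = fit.design.terms[1].years[0]
        before = annual_hotspot(fit, mesh, dom, y0)
        fit.grid[0].x_mode = fit.grid[0].x_mode + 10.0
        after = annual_hotspot(fit, mesh, dom, y0)
        fit.grid[0].x_mode = fit.grid[0].x_mode - 10.0
        assert before[:2] == after[:2]

    def test_zero_bycatch_year_missing(self, replicated_fit):
        obs, fit, mesh, dom = replicated_fit
        y0 = fit.design.terms[1].years[0]
        assert annual_hotspot(fit, mesh, dom, y0,
                              zero_bycatch_years=[y0]) is None
        track = hotspot_track(fit, mesh, dom, zero_bycatch_years=[y0])
        assert bool(track.loc[track.year == y0, "missing"].iloc[0])

    def test_year_outside_range(self, replicated_fit):
        obs, fit, mesh, dom = replicated_fit
        with pytest.raises(ValueError):
            annual_hotspot(fit, mesh, dom, 1234)

    def test_zero_bycatch_years_helper(self):
        df = pd.DataFrame({"year": [2000, 2000, 2001, 2002],
                           "bycatch": [0, 2, 0, 1]})
        assert zero_bycatch_years(df) == [2001]


class TestCCF:
    def _track(self, years, lats):
        return pd.DataFrame({"year": years, "lat": lats,
                             "lon": 0.0, "value": 0.0,
                             "missing": [not np.isfinite(v) for v in lats]})

    def test_perfect_lag_two(self):
        years = np.arange(2000, 2020)
        idx = ClimateSeries(np.arange(1998, 2020),
                            np.sin(np.arange(1998, 2020) * 2.3))
        lats = [idx.value(y - 2) for y in years]
        ccf = ccf_lagged(self._track(years, lats), idx, max_lag=3)
        row = ccf.set_index("lag").loc[2]
        assert row["r"] == pytest.approx(1.0)
        assert bool(row["significant"])

    def test_constant_latitude_not_computable(self):
        years = np.arange(2000, 2015)
        idx = ClimateSeries(years, np.random.default_rng(0).normal(size=15))
        ccf = ccf_lagged(self._track(years, np.full(15, 36.0)), idx)
        assert not ccf["computable"].any()

    def test_insufficient_overlap_flagged(self):
        years = np.arange(2000, 2006)          # only 6 hotspot years
        idx = ClimateSeries(years, np.arange(6.0))
        ccf = ccf_lagged(self._track(years, np.arange(6.0) + 30), idx)
        assert not ccf["computable"].any()

    def test_null_false_positive_rate_in_expected_band(self):
        rng = np.random.default_rng(123)
        years = np.arange(1992, 2018)
        hits = 0
        n = 1000
        for _ in range(n):
            idx = ClimateSeries(years, rng.standard_normal(26))
            lats = 36 + rng.standard_normal(26)
            ccf = ccf_lagged(self._track(years, lats), idx, max_lag=0)
            hits += int(ccf.loc[0, "significant"])
        assert 0.025 < hits / n < 0.08

    def test_overlap_count_decreases_with_lag(self):
        years = np.arange(2000, 2016)
        idx = ClimateSeries(years, np.random.default_rng(1).normal(size=16))
        lats = np.random.default_rng(2).normal(size=16) + 36
        ccf = ccf_lagged(self._track(years, lats), idx, max_lag=4)
        assert (np.diff(ccf["n"]) <= 0).all()
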