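"""Hurdle-model fitting: analytic oracles, MCMC cross-check, DIC/WAIC, selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.special import expit, logit

import bycatch.hurdle as hd
from bycatch.hurdle import (BoundaryWarning, ModelSpec, PriorSpec,
                            SeparationError, build_design, compute_dic,
                            compute_waic, fit_bernoulli, fit_hurdle,
                            fit_ztpoisson, stepwise_select, _eta_draws)
from bycatch.mesh import build_mesh
from bycatch.terms import UnseenLevelError


def _df(bycatch, **cols):
    d = {"bycatch": np.asarray(bycatch), "year": 2000}
    d.update(cols)
    return pd.DataFrame(d)


class TestDesign:
    def test_categorical_coded_with_level_columns_summing_to_zero(
            self, observer_data):
        spec = ModelSpec(probability_terms=["season"])
        dz, _ = build_design(observer_data, spec)
        assert dz.slices["season"].stop - dz.slices["season"].start == 4
        fit = fit_bernoulli(dz)
        season = fit.posterior_mean_latent()[dz.slices["season"]]
        # the soft sum-to-zero constraint pins the level sum near zero
        assert abs(season.sum()) < 1e-2

    def test_rw1_structure_rank_deficiency(self, observer_data):
        spec = ModelSpec(probability_terms=["water_temp"])
        dz, _ = build_design(observer_data, spec)
        smooth = dz.terms[1]
        R = smooth.structure_matrix().toarray()
        assert R.shape == (20, 20)
        assert np.linalg.matrix_rank(R) == 19

    def test_unknown_covariate_rejected(self, observer_data):
        with pytest.raises(ValueError):
            build_design(observer_data,
                         ModelSpec(probability_terms=["no_such_col"]))

    def test_unseen_level_at_prediction(self, observer_data):
        spec = ModelSpec(probability_terms=["season"])
        dz, _ = build_design(observer_data, spec)
        new = observer_data.head(3).copy()
        new["season"] = "monsoon"
        with pytest.raises(UnseenLevelError):
            dz.design_for(new)

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(probability_terms=["season", "season"])

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            build_design(pd.DataFrame(columns=["bycatch", "year"]),
                         ModelSpec())


class TestBernoulliFit:
    def test_intercept_only_matches_logit_of_rate(self):
        # 92 positive of 19,811 sets: the mode should sit at logit(92/19811)
        y = np.zeros(19811, dtype=int)
        y[:92] = 1
        dz, _ = build_design(_df(y), ModelSpec())
        fit = fit_bernoulli(dz)
        assert fit.posterior_mean_latent()[0] == pytest.approx(
            logit(92 / 19811), abs=0.02)

    def test_response_validation(self):
        dz, _ = build_design(_df([0, 2, 1, 1]), ModelSpec())
        dz.y = np.array([0.0, 2.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            fit_bernoulli(dz)

    def test_separation_signaled(self, monkeypatch):
        rng = np.random.default_rng(0)
        x = np.repeat([0.0, 1.0], 100)
        y = (x > 0.5).astype(int)          # perfectly separated
        df = _df(y, sep=x)
        dz, _ = build_design(df, ModelSpec(probability_terms=["raw:sep"]))
        monkeypatch.setattr(hd, "LINPRED_BOUND", 6.0)
        with pytest.raises((SeparationError, hd.ConvergenceError)):
            fit_bernoulli(dz)

    def test_laplace_matches_mcmc_oracle(self, rng):
        """Random-walk Metropolis on a 2-parameter model as posterior oracle."""
        n = 600
        x = rng.standard_normal(n)
        eta_true = -1.0 + 0.8 * x
        y = (rng.uniform(size=n) < expit(eta_true)).astype(int)
        df = _df(y, x=x)
        dz, _ = build_design(df, ModelSpec(probability_terms=["raw:x"]))
        fit = fit_bernoulli(dz)
        mean = fit.posterior_mean_latent()
        sd = fit.posterior_latent_sd([0, 1])

        def logpost(beta):
            eta = beta[0] + beta[1] * x
            return (y * eta - np.logaddexp(0, eta)).sum() \
                - 0.5 * (beta ** 2).sum() / 31.6 ** 2

        chain = np.zeros((40000, 2))
        cur = np.zeros(2)
        lp = logpost(cur)
        mrng = np.random.default_rng(1)
        for i in range(len(chain)):
            prop = cur + 0.35 * mrng.standard_normal(2)
            lp2 = logpost(prop)
            if np.log(mrng.uniform()) < lp2 - lp:
                cur, lp = prop, lp2
            chain[i] = cur
        mcmc_mean = chain[5000:].mean(axis=0)
        assert np.all(np.abs(mean - mcmc_mean) < 0.05 * sd + 0.02)


class TestZTPoissonFit:
    def test_intercept_only_solves_truncated_mean_equation(self):
        # mean positive count 165/92 birds per set
        counts = np.ones(92, dtype=int)
        counts[:61] += 1
        counts[:12] += 1
        assert counts.sum() == 165
        _, dy = build_design(_df(counts), ModelSpec())
        fit = fit_ztpoisson(dy)
        lam_hat = np.exp(fit.posterior_mean_latent()[0])
        ybar = 165 / 92
        lam_star = brentq(lambda l: l / (1 - np.exp(-l)) - ybar, 1e-8, 20)
        assert lam_hat == pytest.approx(lam_star, abs=0.01)

    def test_all_ones_signals_boundary(self):
        _, dy = build_design(_df(np.ones(60, dtype=int)), ModelSpec())
        with pytest.warns(BoundaryWarning):
            fit_ztpoisson(dy)

    def test_zero_response_rejected(self):
        _, dy = build_design(_df([1, 2, 1]), ModelSpec())
        dy.y = np.array([1.0, 0.0, 2.0])
        with pytest.raises(ValueError):
            fit_ztpoisson(dy)

    def test_known_rate_recovered(self, rng):
        from bycatch.synth import sample_ztpoisson
        lam = 2.5
        y = sample_ztpoisson(np.full(400, lam), rng)
        _, dy = build_design(_df(y), ModelSpec())
        fit = fit_ztpoisson(dy)
        lam_hat = np.exp(fit.posterior_mean_latent()[0])
        assert lam_hat == pytest.approx(lam, rel=0.1)


class TestCriteria:
    def test_degenerate_posterior_gives_zero_pd(self):
        y = np.array([0, 1, 0, 0, 1])
        dz, _ = build_design(_df(y), ModelSpec())
        fit = fit_bernoulli(dz)
        eta = np.tile(fit.posterior_mean_eta(), (5, 1))   # point mass
        dev = -2 * fit.design.likelihood.loglik(fit.design.y, eta[0]).sum()
        assert compute_dic(fit, eta_draws=eta) == pytest.approx(dev, abs=1e-9)
        # WAIC of a point mass: p_waic = 0, lppd = loglik at the point
        assert compute_waic(fit, eta_draws=eta) == pytest.approx(dev, abs=1e-9)

    def test_needs_two_draws(self):
        y = np.array([0, 1, 0])
        dz, _ = build_design(_df(y), ModelSpec())
        fit = fit_bernoulli(dz)
        with pytest.raises(ValueError):
            compute_dic(fit, n_draws=1)
        with pytest.raises(ValueError):
            compute_waic(fit, eta_draws=np.zeros((1, 3)))

    def test_dic_matches_quadrature_oracle(self, rng):
        """Intercept-only Bernoulli: dense 1-d numeric integration as oracle."""
        n, k = 400, 90
        y = np.zeros(n)
        y[:k] = 1
        dz, _ = build_design(_df(y), ModelSpec())
        fit = fit_bernoulli(dz)
        dic = compute_dic(fit, eta_draws=_eta_draws(fit, 4000, 0))

        theta = np.linspace(-3, 1, 4001)
        loglik = k * theta - n * np.logaddexp(0, theta)
        logpost = loglik - 0.5 * theta ** 2 / 31.6 ** 2
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        dbar = np.sum(w * (-2 * loglik))
        eta_bar = np.sum(w * theta)
        dhat = -2 * (k * eta_bar - n * np.logaddexp(0, eta_bar))
        oracle = 2 * dbar - dhat
        assert dic == pytest.approx(oracle, abs=0.5)

    def test_pure_noise_covariate_moves_waic_little(self, rng):
        hits = 0
        n_sims = 20
        for s in range(n_sims):
            r = np.random.default_rng(s)
            y = (r.uniform(size=600) < 0.15).astype(int)
            noise = r.integers(0, 3, size=600).astype(str)
            df = _df(y, noise=noise)
            d0, _ = build_design(df, ModelSpec())
            f0 = fit_bernoulli(d0)
            w0 = compute_waic(f0, eta_draws=_eta_draws(f0, 400, s))
            d1, _ = build_design(df, ModelSpec(probability_terms=["cat:noise"]))
            f1 = fit_bernoulli(d1)
            w1 = compute_waic(f1, eta_draws=_eta_draws(f1, 400, s))
            if abs(w1 - w0) < 5:
                hits += 1
        assert hits >= 0.9 * n_sims


class TestSpatialDegenerate:
    def test_tiny_sigma_field_matches_nonspatial_fit(self, observer_data,
                                                     domain, monkeypatch):
        from bycatch.terms import FieldTerm
        mesh = build_mesh(domain, 300.0, 600.0, extension_km=300.0)
        obs = observer_data.head(4000)
        spec_sp = ModelSpec(probability_terms=["season", "spatial"])
        spec_ns = ModelSpec(probability_terms=["season"])
        monkeypatch.setattr(
            FieldTerm, "hyper_init",
            lambda self: {"log_range": np.log(500.0), "log_sigma": -7.0})
        dz_sp, _ = build_design(obs, spec_sp, mesh=mesh, domain=domain)
        f_sp = fit_bernoulli(dz_sp, optimize_hypers=False, grid_levels=1)
        dz_ns, _ = build_design(obs, spec_ns)
        f_ns = fit_bernoulli(dz_ns)
        a = f_sp.posterior_mean_latent()[dz_sp.slices["season"]]
        b = f_ns.posterior_mean_latent()[dz_ns.slices["season"]]
        np.testing.assert_allclose(a, b, atol=0.02)


class TestYearReplicatedField:
    def test_permuting_year_labels_permutes_fields(self, domain):
        from bycatch.synth import (TruthParams, gen_fleet, gen_observer_data,
                                   gen_climate_series,
                                   make_bump_field_sampler)
        truth = TruthParams(base_positive_fraction=0.03, vessel_sd=0.0,
                            field_amplitude=3.0)
        clim = gen_climate_series(range(2002, 2012), seed=3)
        fleet = gen_fleet(domain, truth, 4000, range(2004, 2008), seed=2)
        obs = gen_observer_data(fleet, truth,
                                make_bump_field_sampler(domain, truth, clim),
                                1.0, seed=3)
        mesh = build_mesh(domain, 300.0, 600.0, extension_km=300.0)
        spec = ModelSpec(probability_terms=["spatial_t"])
        kw = dict(optimize_hypers=False, grid_levels=1)

        dz, _ = build_design(obs, spec, mesh=mesh, domain=domain)
        fit = fit_bernoulli(dz, **kw)
        years = dz.terms[1].years
        k = mesh.n_nodes
        blocks = {y: fit.posterior_mean_latent()[
            dz.slices["spatial_t"]][j * k:(j + 1) * k]
            for j, y in enumerate(years)}

        # swap the labels of the first two years and refit
        obs2 = obs.copy()
        y0, y1 = years[0], years[1]
        sel0 = obs2["year"] == y0
        sel1 = obs2["year"] == y1
        obs2.loc[sel0, "year"] = y1
        obs2.loc[sel1, "year"] = y0
        dz2, _ = build_design(obs2, spec, mesh=mesh, domain=domain)
        fit2 = fit_bernoulli(dz2, **kw)
        blocks2 = {y: fit2.posterior_mean_latent()[
            dz2.slices["spatial_t"]][j * k:(j + 1) * k]
            for j, y in enumerate(dz2.terms[1].years)}
        np.testing.assert_allclose(blocks[y0], blocks2[y1], atol=1e-6)
        np.testing.assert_allclose(blocks[y1], blocks2[y0], atol=1e-6)


class TestStepwise:
    def test_trace_dic_monotone_nonincreasing(self, observer_data):
        spec, trace = stepwise_select(
            observer_data.head(5000), ["season", "set_time"], ["haul_time"],
            seed=1, n_criteria_draws=300)
        dics = trace["DIC_z"].to_numpy()
        assert np.all(np.diff(dics) <= 1e-9)

    def test_pure_noise_candidates_rejected(self, observer_data):
        obs = observer_data.head(5000).copy()
        r = np.random.default_rng(11)
        obs["noiseA"] = r.integers(0, 4, len(obs)).astype(str)
        obs["noiseB"] = r.integers(0, 4, len(obs)).astype(str)
        spec, _ = stepwise_select(obs, ["cat:noiseA", "cat:noiseB"], [],
                                  seed=2, n_criteria_draws=500)
        assert spec.probability_terms == []


def test_fit_hurdle_reports_both_components(observer_data):
    fit = fit_hurdle(observer_data.head(6000),
                     ModelSpec(probability_terms=["season"],
                               positive_terms=["haul_time"]),
                     seed=5)
    for v in (fit.dic_z, fit.dic_y, fit.waic_z, fit.waic_y):
        assert np.isfinite(v)
    assert fit.z.weights == pytest.approx([1.0])
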