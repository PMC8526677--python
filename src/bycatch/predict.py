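"""Posterior draws and fleet-wide bycatch extrapolation.

Per posterior draw and per longline set the expected bycatch is
``E[y] = p * λ / (1 - e^{-λ})`` — occurrence probability times the
zero-truncated-Poisson mean — evaluated at the set's covariates and location.
Group totals are summed within draw, then summarized across draws, so group
CVs reflect the correlated posterior uncertainty of their members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from bycatch.hurdle import HurdleFit, SubFit, _zt_mean
from bycatch.terms import FieldTerm, VesselTerm

log = logging.getLogger(__name__)


@dataclass
class PosteriorDraws:
    """Joint latent draws for both sub-models (grid-mixture Gaussian)."""

    n_draws: int
    seed: int
    xz: np.ndarray              # (n_draws, m_z)
    xy: np.ndarray              # (n_draws, m_y)
    grid_z: np.ndarray          # grid-point index per draw
    grid_y: np.ndarray
    fit: HurdleFit


def _sample_sub(fit: SubFit, n: int, rng: np.random.Generator):
    w = fit.weights
    idx = rng.choice(len(w), size=n, p=w / w.sum())
    x = np.empty((n, fit.design.n_latent))
    for k in np.unique(idx):
        sel = np.flatnonzero(idx == k)
        g = fit.grid[k]
        x[sel] = g.factor.sample(rng, sel.size, mean=g.x_mode)
    return x, idx


def posterior_draws(fit: HurdleFit, n: int = 1000,
                    seed: int = 0) -> PosteriorDraws:
    """Seeded draws from the approximated posterior of both sub-models."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    xz, gz = _sample_sub(fit.z, n, rng)
    xy, gy = _sample_sub(fit.y, n, rng)
    return PosteriorDraws(n_draws=n, seed=seed, xz=xz, xy=xy,
                          grid_z=gz, grid_y=gy, fit=fit)


@dataclass
class SetExpectations:
    """Per-draw, per-set expected bycatch with validity flags."""

    values: np.ndarray          # (n_draws, n_sets), NaN-free; invalid cols zeroed
    valid: np.ndarray           # (n_sets,) bool; False => outside mesh, excluded
    sets: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return int((~self.valid).sum())


def _vessel_population_effects(design, df, x_draws, grid_idx, fit: SubFit,
                               rng: np.random.Generator) -> np.ndarray:
    """Per-draw effects for vessels unseen in training, N(0, 1/τ) per vessel."""
    eta_add = np.zeros((x_draws.shape[0], len(df)))
    for term in design.terms:
        if not isinstance(term, VesselTerm):
            continue
        unseen = term.unseen_mask(df)
        if not unseen.any():
            continue
        log.info("%d sets with unseen vessel; drawing population effects",
                 int(unseen.sum()))
        ids = df.loc[unseen, term.column].to_numpy()
        uniq = pd.unique(ids)
        pos = {v: np.flatnonzero(unseen)[ids == v] for v in uniq}
        for s in range(x_draws.shape[0]):
            g = fit.grid[grid_idx[s]]
            tau = np.exp(g.hypers.get(term.name, {}).get("log_tau", 0.0))
            effs = rng.normal(0.0, tau ** -0.5, size=len(uniq))
            for v, e in zip(uniq, effs):
                eta_add[s, pos[v]] = e
    return eta_add


def expected_bycatch_per_set(draws: PosteriorDraws, sets: pd.DataFrame,
                             seed: int | None = None) -> SetExpectations:
    """Per-draw expected bycatch for each set: p · λ/(1−e^{−λ}).

    Sets outside the mesh are flagged invalid and their expectations zeroed
    (excluded from totals); vessels unseen in training receive effects drawn
    from the vessel-effect population distribution.
    """
    fit = draws.fit
    rng = np.random.default_rng(draws.seed + 1 if seed is None else seed)

    Bz = fit.z.design.design_for(sets)
    valid = np.ones(len(sets), dtype=bool)
    for term in fit.z.design.terms:
        if isinstance(term, FieldTerm) and hasattr(term, "last_valid"):
            valid &= term.last_valid
    eta_z = (Bz @ draws.xz.T).T
    eta_z += _vessel_population_effects(fit.z.design, sets, draws.xz,
                                        draws.grid_z, fit.z, rng)

    By = fit.y.design.design_for(sets)
    for term in fit.y.design.terms:
        if isinstance(term, FieldTerm) and hasattr(term, "last_valid"):
            valid &= term.last_valid
    eta_y = (By @ draws.xy.T).T
    eta_y += _vessel_population_effects(fit.y.design, sets, draws.xy,
                                        draws.grid_y, fit.y, rng)

    p = 1.0 / (1.0 + np.exp(-eta_z))
    lam = np.exp(np.minimum(eta_y, 30.0))
    e = p * _zt_mean(lam)
    if not valid.all():
        log.info("%d sets outside the mesh excluded from totals",
                 int((~valid).sum()))
        e[:, ~valid] = 0.0
    return SetExpectations(values=e, valid=valid, sets=sets)


def single_draw_scorer(draws: PosteriorDraws):
    """Callable (sets_df, draw_index) -> per-set expected bycatch.

    Used by the mitigation engine to re-score relocated sets under one
    posterior draw.  Vessels unseen in training contribute their population
    mean (zero) here, keeping the scorer deterministic.
    """
    fit = draws.fit

    def scorer(df: pd.DataFrame, d: int) -> np.ndarray:
        eta_z = fit.z.design.design_for(df) @ draws.xz[d]
        eta_y = fit.y.design.design_for(df) @ draws.xy[d]
        p = 1.0 / (1.0 + np.exp(-eta_z))
        lam = np.exp(np.minimum(eta_y, 30.0))
        return p * _zt_mean(lam)

    return scorer


def per_set_summary(expect: SetExpectations) -> pd.DataFrame:
    """Posterior mean and sd of expected bycatch per set."""
    return pd.DataFrame({
        "set_id": expect.sets["set_id"].to_numpy(),
        "mean": expect.values.mean(axis=0),
        "sd": expect.values.std(axis=0, ddof=1),
        "valid": expect.valid,
    })


def aggregate(expect: SetExpectations, by: str | None = None) -> pd.DataFrame:
    """Group totals: sum within draw, then mean/sd/CV across draws.

    ``by`` is a column of the scored sets (year, zone, season, target) or
    None for the overall total.
    """
    vals = expect.values
    if by is None:
        groups = {"total": np.ones(vals.shape[1], dtype=bool)}
    else:
        if by not in expect.sets.columns:
            raise KeyError(f"grouping column {by!r} missing from sets")
        keys = expect.sets[by].to_numpy()
        groups = {k: keys == k for k in pd.unique(keys)}
    rows = []
    for name, mask in groups.items():
        per_draw = vals[:, mask & expect.valid].sum(axis=1)
        mean = float(per_draw.mean())
        sd = float(per_draw.std(ddof=1)) if len(per_draw) > 1 else 0.0
        rows.append({
            "group": name,
            "n_sets": int((mask & expect.valid).sum()),
            "mean": mean,
            "sd": sd,
            "cv": sd / mean if mean > 0 else np.nan,
        })
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
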