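"""Fleet-behavior mitigation scenarios: removal or redistribution of effort.

Six scenarios mirror removal of longline sets from bycatch-hotspot areas
and/or high-bycatch seasons, and redistribution of the same sets to sites at
least 50 miles from every hotspot cell (optionally re-seasoned to spring).
Each repetition samples the affected sets (and one posterior draw) anew; the
percent change in predicted seabird bycatch and in per-species fish catch is
scored against the unmodified-fleet baseline under the same posterior draw.

Hotspot areas are the top-decile cells of the hindcast per-set expected
bycatch surface on a regular grid over the domain.  Fish catch at relocated
sets comes from a k-nearest-neighbour stand-in predictor (mean catch among
same-season, same-target logbook sets around the destination).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from bycatch.geometry import DomainSpec

log = logging.getLogger(__name__)

MILES_TO_KM = 1.609344
SUMMER_SPRING = ("summer", "spring")
SUMMER_WINTER = ("summer", "fall", "winter")   # "summer through winter"

SOURCE_FILTERS = ("hotspot_area", "summer_spring",
                  "hotspot_and_summer_winter", "summer_winter")
DEST_RULES = ("neighbor_sites_ge_50mi", "spring_season",
              "spring_and_neighbor_sites")


@dataclass
class ScenarioSpec:
    """One fleet-behavior scenario."""

    id: int
    action: str                       # remove | redistribute
    source_filter: str
    destination_rule: str | None = None
    n_sets: int = 5000
    n_reps: int = 1000
    min_move_distance_mi: float = 50.0
    hotspot_quantile: float = 0.9

    def __post_init__(self):
        if self.action not in ("remove", "redistribute"):
            raise ValueError(f"unknown action {self.action}")
        if self.source_filter not in SOURCE_FILTERS:
            raise ValueError(f"unknown source filter {self.source_filter}")
        if (self.destination_rule is not None) != (self.action == "redistribute"):
            raise ValueError("destination rule present iff action=redistribute")
        if self.destination_rule is not None and \
                self.destination_rule not in DEST_RULES:
            raise ValueError(f"unknown destination rule {self.destination_rule}")


def default_scenarios(n_sets: int = 5000, n_reps: int = 1000) -> list:
    """The six study scenarios: three removals, three redistributions."""
    mk = lambda i, a, s, d=None: ScenarioSpec(i, a, s, d, n_sets, n_reps)
    return [
        mk(1, "remove", "hotspot_area"),
        mk(2, "remove", "summer_spring"),
        mk(3, "remove", "hotspot_and_summer_winter"),
        mk(4, "redistribute", "hotspot_area", "neighbor_sites_ge_50mi"),
        mk(5, "redistribute", "summer_winter", "spring_season"),
        mk(6, "redistribute", "hotspot_and_summer_winter",
           "spring_and_neighbor_sites"),
    ]


# ---------------------------------------------------------------------------
# bycatch surface and hotspot mask
# ---------------------------------------------------------------------------

@dataclass
class GridSurface:
    """Regular lon/lat grid over the domain with a per-cell value."""

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    value: np.ndarray            # (n_lat, n_lon), NaN for empty cells
    domain: DomainSpec

    def cell_of(self, lon, lat):
        i = np.clip(np.digitize(lat, self.lat_edges) - 1, 0,
                    len(self.lat_edges) - 2)
        j = np.clip(np.digitize(lon, self.lon_edges) - 1, 0,
                    len(self.lon_edges) - 2)
        return i, j

    def centers(self):
        clon = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        clat = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        return np.meshgrid(clon, clat)


def bycatch_surface(fleet: pd.DataFrame, per_set_mean: np.ndarray,
                    domain: DomainSpec, cell_deg: float = 1.0) -> GridSurface:
    """Mean predicted per-set expected bycatch on a regular grid."""
    minx, miny, maxx, maxy = domain.boundary.bounds
    lon_edges = np.arange(minx, maxx + cell_deg, cell_deg)
    lat_edges = np.arange(miny, maxy + cell_deg, cell_deg)
    sums = np.zeros((len(lat_edges) - 1, len(lon_edges) - 1))
    counts = np.zeros_like(sums)
    i = np.clip(np.digitize(fleet["lat"], lat_edges) - 1, 0, sums.shape[0] - 1)
    j = np.clip(np.digitize(fleet["lon"], lon_edges) - 1, 0, sums.shape[1] - 1)
    np.add.at(sums, (i, j), per_set_mean)
    np.add.at(counts, (i, j), 1.0)
    with np.errstate(invalid="ignore"):
        value = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return GridSurface(lon_edges, lat_edges, value, domain)


def hotspot_mask(surface: GridSurface, quantile: float = 0.9) -> np.ndarray:
    """Boolean mask of cells at or above the value quantile (NaN cells False)."""
    vals = surface.value
    finite = np.isfinite(vals)
    if not finite.any():
        warnings.warn("surface has no populated cells; empty hotspot mask")
        return np.zeros_like(vals, dtype=bool)
    v = vals[finite]
    if quantile > 0 and v.max() == v.min():
        warnings.warn("degenerate constant surface; empty hotspot mask")
        return np.zeros_like(vals, dtype=bool)
    thresh = np.quantile(v, quantile)
    mask = np.zeros_like(vals, dtype=bool)
    mask[finite] = vals[finite] >= thresh
    return mask


# ---------------------------------------------------------------------------
# stand-in catch predictor
# ---------------------------------------------------------------------------

class KNNCatchModel:
    """k-nearest-neighbour fish-catch predictor for relocated sets.

    Predicted catch of species s for a set is the mean observed catch of the
    k nearest logbook sets with the same season and target species.
    """

    def __init__(self, fleet: pd.DataFrame, domain: DomainSpec, k: int = 25):
        self.k = k
        self.domain = domain
        self.species = [c[len("catch_"):] for c in fleet.columns
                        if c.startswith("catch_")]
        self._trees = {}
        for (season, target), grp in fleet.groupby(["season", "target"]):
            x, y = domain.to_planar(grp["lon"].to_numpy(), grp["lat"].to_numpy())
            tree = cKDTree(np.column_stack([x, y]))
            catches = grp[[f"catch_{s}" for s in self.species]].to_numpy(float)
            self._trees[(season, target)] = (tree, catches)

    def predict(self, sets: pd.DataFrame) -> np.ndarray:
        """(n_sets, n_species) predicted catch counts."""
        out = np.zeros((len(sets), len(self.species)))
        x, y = self.domain.to_planar(sets["lon"].to_numpy(),
                                     sets["lat"].to_numpy())
        pts = np.column_stack([x, y])
        for key, sel in sets.groupby(["season", "target"]).groups.items():
            pos = sets.index.get_indexer(sel)
            if key not in self._trees:   # fall back to pooled neighbours
                key = next(iter(self._trees))
            tree, catches = self._trees[key]
            k = min(self.k, tree.n)
            _, nn = tree.query(pts[pos], k=k)
            nn = np.atleast_2d(nn)
            out[pos] = catches[nn].mean(axis=1)
        return out


# ---------------------------------------------------------------------------
# scenario engine
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    per_rep: pd.DataFrame          # one row per repetition
    n_aborted: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in self.per_rep.columns:
            v = self.per_rep[col].to_numpy()
            rows.append({"scenario": self.spec.id, "metric": col,
                         "mean": float(np.mean(v)),
                         "lo95": float(np.quantile(v, 0.025)),
                         "hi95": float(np.quantile(v, 0.975))})
        return pd.DataFrame(rows)


def _source_mask(fleet: pd.DataFrame, spec: ScenarioSpec,
                 in_hotspot: np.ndarray) -> np.ndarray:
    season = fleet["season"].to_numpy()
    if spec.source_filter == "hotspot_area":
        return in_hotspot
    if spec.source_filter == "summer_spring":
        return np.isin(season, SUMMER_SPRING)
    if spec.source_filter == "summer_winter":
        return np.isin(season, SUMMER_WINTER)
    return in_hotspot & np.isin(season, SUMMER_WINTER)


def eligible_destinations(surface: GridSurface, mask: np.ndarray,
                          min_move_distance_mi: float) -> np.ndarray:
    """Centers (lon, lat) of water cells ≥ the distance from all hotspot cells."""
    LON, LAT = surface.centers()
    lon = LON.ravel()
    lat = LAT.ravel()
    water = surface.domain.in_water(lon, lat)
    hot = mask.ravel()
    if not hot.any():
        return np.column_stack([lon[water], lat[water]])
    x, y = surface.domain.to_planar(lon, lat)
    pts = np.column_stack([x, y])
    tree = cKDTree(pts[hot])
    d, _ = tree.query(pts, k=1)
    keep = water & (d >= min_move_distance_mi * MILES_TO_KM)
    return np.column_stack([lon[keep], lat[keep]])


def run_scenario(fleet: pd.DataFrame, base_expect: np.ndarray,
                 spec: ScenarioSpec, surface: GridSurface, seed: int,
                 scorer=None, catch_model: KNNCatchModel | None = None,
                 mask: np.ndarray | None = None) -> ScenarioResult:
    """Run one scenario for ``spec.n_reps`` seeded repetitions.

    ``base_expect`` is the (n_draws, n_sets) per-draw expected bycatch of the
    unmodified fleet; each repetition scores against one of its draws.
    ``scorer(sets_df, draw_index)`` returns per-set expected bycatch for
    relocated sets under that draw (required for redistribution scenarios).
    """
    if spec.action == "redistribute" and scorer is None:
        raise ValueError("redistribution scenarios need a scorer")
    mask = hotspot_mask(surface, spec.hotspot_quantile) if mask is None else mask
    i, j = surface.cell_of(fleet["lon"].to_numpy(), fleet["lat"].to_numpy())
    in_hotspot = mask[i, j]
    src = _source_mask(fleet, spec, in_hotspot)
    src_idx = np.flatnonzero(src)

    species_cols = [c for c in fleet.columns if c.startswith("catch_")]
    catch_total = fleet[species_cols].to_numpy(float)
    base_catch = catch_total.sum(axis=0)

    dests = None
    if spec.action == "redistribute" and \
            spec.destination_rule != "spring_season":
        dests = eligible_destinations(surface, mask, spec.min_move_distance_mi)

    n_draws = base_expect.shape[0]
    rows = []
    n_aborted = 0
    # repetitions are keyed by (seed, source filter, rep), not scenario id, so
    # scenarios sharing a source filter sample identical sets per repetition
    # (paired removal-vs-redistribution comparisons)
    src_key = SOURCE_FILTERS.index(spec.source_filter)
    for rep in range(spec.n_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, src_key, rep]))
        d = int(rng.integers(n_draws))
        base_total = float(base_expect[d].sum())
        take = min(spec.n_sets, src_idx.size)
        chosen = rng.choice(src_idx, size=take, replace=False)
        removed = float(base_expect[d, chosen].sum())
        removed_catch = catch_total[chosen].sum(axis=0)

        if spec.action == "remove":
            new_total = base_total - removed
            new_catch = base_catch - removed_catch
        else:
            moved = fleet.iloc[chosen].copy().reset_index(drop=True)
            if spec.destination_rule in ("spring_season",
                                         "spring_and_neighbor_sites"):
                moved["season"] = "spring"
            if spec.destination_rule in ("neighbor_sites_ge_50mi",
                                         "spring_and_neighbor_sites"):
                if dests is None or len(dests) == 0:
                    n_aborted += 1
                    continue
                pick = rng.integers(len(dests), size=take)
                cell = 0.5 * float(np.diff(surface.lon_edges[:2])[0])
                moved["lon"] = dests[pick, 0] + rng.uniform(-cell, cell, take)
                moved["lat"] = dests[pick, 1] + rng.uniform(-cell, cell, take)
                moved["zone"] = surface.domain.zone_of(
                    moved["lon"].to_numpy(), moved["lat"].to_numpy())
            new_expect = np.asarray(scorer(moved, d), dtype=float)
            new_total = base_total - removed + float(new_expect.sum())
            if catch_model is not None:
                new_catch = (base_catch - removed_catch
                             + catch_model.predict(moved).sum(axis=0))
            else:
                new_catch = base_catch
        row = {"pct_bycatch_change": 100.0 * (new_total - base_total)
               / base_total if base_total > 0 else 0.0,
               "pct_catch_change": 100.0 * (new_catch.sum() - base_catch.sum())
               / base_catch.sum()}
        for s_col, b, nw in zip(species_cols, base_catch, new_catch):
            sp_name = s_col[len("catch_"):]
            row[f"pct_catch_change_{sp_name}"] = \
                100.0 * (nw - b) / b if b > 0 else 0.0
        rows.append(row)
    if n_aborted:
        log.warning("scenario %d: %d repetitions aborted (no eligible "
                    "destinations)", spec.id, n_aborted)
    return ScenarioResult(spec=spec, per_rep=pd.DataFrame(rows),
                          n_aborted=n_aborted)


def summarize_scenarios(results: list) -> pd.DataFrame:
    """Mean % changes with 95% intervals, ordered by bycatch reduction."""
    if not results:
        raise ValueError("no scenario results")
    tab = pd.concat([r.summary() for r in results], ignore_index=True)
    order = (tab[tab.metric == "pct_bycatch_change"]
             .sort_values("mean")["scenario"].tolist())
    tab["order"] = tab["scenario"].map({s: k for k, s in enumerate(order)})
    return tab.sort_values(["order", "metric"]).drop(columns="order") \
              .reset_index(drop=True)
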