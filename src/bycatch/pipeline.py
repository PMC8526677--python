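"""Configuration and end-to-end orchestration of the bycatch analysis.

Stages: simulate → mesh → select → fit/predict → hotspot → mitigate.  Every
stage is independently invokable (via :mod:`bycatch.cli`) and reads its
inputs from the artifacts of earlier stages; ``run_pipeline`` executes all of
them, sharing fitted models in memory.  A single master seed fans out to
per-stage seeds through a documented counter scheme, so every artifact is
regenerated bit-identically from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bycatch import geometry, synth
from bycatch.geometry import DomainSpec, HIGH_BYCATCH_ZONES, gen_domain, subdomain
from bycatch.hotspot import ccf_lagged, hotspot_track, zero_bycatch_years
from bycatch.hurdle import (ModelSpec, PriorSpec, fit_hurdle, stepwise_select)
from bycatch.mesh import BarrierMesh, build_mesh
from bycatch.mitigation import (KNNCatchModel, bycatch_surface,
                                default_scenarios, hotspot_mask, run_scenario,
                                summarize_scenarios)
from bycatch.predict import (aggregate, expected_bycatch_per_set,
                             per_set_summary, posterior_draws,
                             single_draw_scorer)
from bycatch.synth import (ClimateSeries, TruthParams, gen_climate_series,
                           gen_fleet, gen_observer_data,
                           make_bump_field_sampler)

log = logging.getLogger(__name__)

STAGES = ("simulate", "mesh", "select", "predict", "hotspot", "mitigate")

REQUIRED_KEYS = ("master_seed", "output_dir")


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (YAML round-trippable)."""

    master_seed: int = 1
    output_dir: str = "results/run"
    # --- simulate ---
    n_fleet: int = 40000
    year_start: int = 2000
    year_end: int = 2015
    coverage: float = 0.30
    climate_ar: float = 0.3
    truth: TruthParams = field(default_factory=TruthParams)
    # --- mesh (km) ---
    max_edge_inner_km: float = 220.0
    max_edge_outer_km: float = 440.0
    extension_km: float = 300.0
    sub_max_edge_inner_km: float = 150.0
    sub_extension_km: float = 250.0
    # --- model selection ---
    run_selection: bool = True
    candidates_z: tuple = ("water_temp", "season", "target", "set_time",
                           "vessel")
    candidates_y: tuple = ("n_hooks", "haul_time")
    spatial_z: tuple = ("spatial",)
    spatial_y: tuple = ()
    delta_dic: float = 5.0
    grid_levels: int = 3
    # fallback/final specs when run_selection is False
    final_spec_z: tuple = ("water_temp", "season", "set_time", "vessel",
                           "spatial")
    final_spec_y: tuple = ("n_hooks", "haul_time")
    sub_spec_z: tuple = ("season", "set_time", "spatial_t")
    sub_spec_y: tuple = ("n_hooks",)
    # --- prediction ---
    n_draws: int = 300
    # --- hotspot ---
    max_lag: int = 5
    # --- mitigation ---
    scenario_n_sets: int = 500
    scenario_n_reps: int = 100
    surface_cell_deg: float = 1.0

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth"] = self.truth.to_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in REQUIRED_KEYS:
            if key not in d:
                raise KeyError(f"missing required config key: {key}")
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        if "truth" in d and isinstance(d["truth"], dict):
            d["truth"] = TruthParams(**d["truth"])
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)

    def write_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def read_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    idx = STAGES.index(stage) if stage in STAGES else 97 + len(stage)
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("set_id", "year", "season", "lon", "lat", "n_hooks")


def validate_inputs(path, domain: DomainSpec | None = None):
    """Validate a longline-set table; exclude and count failing rows.

    Checks per-column missingness, positions inside the study domain (when a
    domain is given) and positive hook counts.  Returns (clean DataFrame,
    report dict).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"unreadable records file {path}: {exc}") from exc
    report = {"n_rows": len(df), "missing_columns": [], "exclusions": {}}
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            report["missing_columns"].append(col)
    if report["missing_columns"]:
        raise ValueError(
            f"missing required column(s): {report['missing_columns']}")
    report["column_missingness"] = {
        c: int(df[c].isna().sum()) for c in df.columns}
    ok = np.ones(len(df), dtype=bool)

    def exclude(mask, reason):
        bad = mask & ok
        if bad.any():
            report["exclusions"][reason] = int(bad.sum())
        ok[bad] = False

    exclude(df["lon"].isna().to_numpy() | df["lat"].isna().to_numpy(),
            "missing position")
    for col in REQUIRED_COLUMNS:
        exclude(df[col].isna().to_numpy(), f"missing {col}")
    exclude((pd.to_numeric(df["n_hooks"], errors="coerce") < 1).to_numpy()
            | pd.to_numeric(df["n_hooks"], errors="coerce").isna().to_numpy(),
            "non-positive hook count")
    if domain is not None:
        pos_ok = df["lon"].notna() & df["lat"].notna()
        bad = np.zeros(len(df), dtype=bool)
        bad[pos_ok.to_numpy()] = ~domain.in_water(
            df.loc[pos_ok, "lon"].to_numpy(), df.loc[pos_ok, "lat"].to_numpy())
        exclude(bad, "position outside study domain")
    report["n_retained"] = int(ok.sum())
    report["n_excluded"] = int((~ok).sum())
    return df[ok].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    """Generate domain, climate, fleet, observer data; write data artifacts."""
    seed = stage_seed(cfg.master_seed, "simulate")
    data = out / "data"
    data.mkdir(parents=True, exist_ok=True)
    domain = gen_domain(seed)
    climate = gen_climate_series(cfg.years, seed + 1, ar=cfg.climate_ar)
    fleet = gen_fleet(domain, cfg.truth, cfg.n_fleet, cfg.years, seed + 2)
    sampler = make_bump_field_sampler(domain, cfg.truth, climate)
    observer = gen_observer_data(fleet, cfg.truth, sampler, cfg.coverage,
                                 seed + 3)
    domain.write_geojson(data / "domain.geojson")
    climate.write_csv(data / "climate.csv")
    synth.write_sets_csv(fleet, data / "fleet.csv")
    synth.write_sets_csv(observer, data / "observer.csv")
    synth.write_truth_yaml(cfg.truth, {"stage": "simulate", "seed": seed},
                           data / "truth.yaml")
    return {"domain": domain, "climate": climate, "fleet": fleet,
            "observer": observer}


def load_data(out: Path) -> dict:
    data = out / "data"
    return {"domain": DomainSpec.read_geojson(data / "domain.geojson"),
            "climate": ClimateSeries.read_csv(data / "climate.csv"),
            "fleet": synth.read_sets_csv(data / "fleet.csv"),
            "observer": synth.read_sets_csv(data / "observer.csv")}


def stage_mesh(cfg: RunConfig, out: Path, domain: DomainSpec) -> dict:
    mdir = out / "mesh"
    mdir.mkdir(parents=True, exist_ok=True)
    mesh_full = build_mesh(domain, cfg.max_edge_inner_km,
                           cfg.max_edge_outer_km, cfg.extension_km)
    sub = subdomain(domain, HIGH_BYCATCH_ZONES)
    mesh_sub = build_mesh(sub, cfg.sub_max_edge_inner_km,
                          cfg.max_edge_outer_km, cfg.sub_extension_km)
    mesh_full.write_json(mdir / "mesh_full.json")
    mesh_sub.write_json(mdir / "mesh_sub.json")
    return {"mesh_full": mesh_full, "mesh_sub": mesh_sub, "sub_domain": sub}


def load_mesh(out: Path, domain: DomainSpec) -> dict:
    mdir = out / "mesh"
    return {"mesh_full": BarrierMesh.read_json(mdir / "mesh_full.json"),
            "mesh_sub": BarrierMesh.read_json(mdir / "mesh_sub.json"),
            "sub_domain": subdomain(domain, HIGH_BYCATCH_ZONES)}


def _priors(cfg: RunConfig, mesh: BarrierMesh) -> PriorSpec:
    span = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
    return PriorSpec(field_range_median=0.5 * float(np.hypot(*span)))


def stage_select(cfg: RunConfig, out: Path, observer: pd.DataFrame,
                 mesh: BarrierMesh, domain: DomainSpec) -> dict:
    sdir = out / "select"
    sdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg.master_seed, "select")
    spec, trace = stepwise_select(
        observer, list(cfg.candidates_z), list(cfg.candidates_y),
        priors=_priors(cfg, mesh), mesh=mesh, domain=domain,
        spatial_z=list(cfg.spatial_z), spatial_y=list(cfg.spatial_y),
        delta=cfg.delta_dic, seed=seed, grid_levels=cfg.grid_levels)
    trace.to_csv(sdir / "trace_full.csv", index=False)
    with open(sdir / "selected.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({"probability_terms": list(spec.probability_terms),
                        "positive_terms": list(spec.positive_terms)}, fh)
    return {"spec": spec, "trace": trace}


def stage_predict(cfg: RunConfig, out: Path, observer: pd.DataFrame,
                  fleet: pd.DataFrame, mesh: BarrierMesh,
                  domain: DomainSpec, spec: ModelSpec) -> dict:
    pdir = out / "predict"
    pdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg.master_seed, "predict")
    fit = fit_hurdle(observer, spec, priors=_priors(cfg, mesh), mesh=mesh,
                     domain=domain, seed=seed, grid_levels=cfg.grid_levels)
    draws = posterior_draws(fit, cfg.n_draws, seed + 1)
    expect = expected_bycatch_per_set(draws, fleet)
    per_set_summary(expect).to_csv(pdir / "per_set.csv", index=False)
    tables = {"total": aggregate(expect)}
    for by in ("year", "zone", "season", "target"):
        tables[by] = aggregate(expect, by=by)
        tables[by].to_csv(pdir / f"totals_by_{by}.csv", index=False)
    tables["total"].to_csv(pdir / "totals_overall.csv", index=False)
    return {"fit": fit, "draws": draws, "expect": expect, "tables": tables}


def stage_hotspot(cfg: RunConfig, out: Path, observer: pd.DataFrame,
                  mesh_sub: BarrierMesh, sub: DomainSpec,
                  climate: ClimateSeries) -> dict:
    hdir = out / "hotspot"
    hdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg.master_seed, "hotspot")
    obs_sub = observer[observer["zone"].isin(HIGH_BYCATCH_ZONES)] \
        .reset_index(drop=True)
    spec = ModelSpec(probability_terms=list(cfg.sub_spec_z),
                     positive_terms=list(cfg.sub_spec_y))
    fit = fit_hurdle(obs_sub, spec, priors=_priors(cfg, mesh_sub),
                     mesh=mesh_sub, domain=sub, seed=seed,
                     grid_levels=cfg.grid_levels)
    zyears = zero_bycatch_years(obs_sub)
    track = hotspot_track(fit.z, mesh_sub, sub, zero_bycatch_years=zyears)
    ccf = ccf_lagged(track, climate, max_lag=cfg.max_lag)
    track.to_csv(hdir / "hotspot_track.csv", index=False)
    ccf.to_csv(hdir / "ccf.csv", index=False)
    return {"fit": fit, "track": track, "ccf": ccf,
            "zero_bycatch_years": zyears}


def stage_mitigate(cfg: RunConfig, out: Path, fleet: pd.DataFrame,
                   domain: DomainSpec, expect, draws) -> dict:
    mdir = out / "mitigate"
    mdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg.master_seed, "mitigate")
    per_set_mean = expect.values.mean(axis=0)
    surface = bycatch_surface(fleet, per_set_mean, domain,
                              cfg.surface_cell_deg)
    scorer = single_draw_scorer(draws)
    catch_model = KNNCatchModel(fleet, domain)
    results = []
    for spec in default_scenarios(cfg.scenario_n_sets, cfg.scenario_n_reps):
        res = run_scenario(fleet, expect.values, spec, surface, seed,
                           scorer=scorer, catch_model=catch_model)
        res.per_rep.assign(scenario=spec.id).to_csv(
            mdir / f"scenario_{spec.id}_reps.csv", index=False)
        results.append(res)
    summary = summarize_scenarios(results)
    summary.to_csv(mdir / "scenario_summary.csv", index=False)
    return {"results": results, "summary": summary}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable run report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=out / "run.log", level=logging.INFO,
                        force=False)
    cfg.write_yaml(out / "config.yaml")
    report = {"config": cfg.to_dict(), "stages": {}, "skipped": []}
    timings = {}
    state = {}

    def run_stage(name, fn, *args, **kw):
        t0 = time.time()
        try:
            res = fn(cfg, out, *args, **kw)
        except Exception as exc:
            raise PipelineError(
                f"stage '{name}' failed: {exc}; partial outputs kept in "
                f"{out}") from exc
        timings[name] = time.time() - t0
        log.info("stage %s done in %.1fs", name, timings[name])
        return res

    state.update(run_stage("simulate", stage_simulate))
    state.update(run_stage("mesh", stage_mesh, state["domain"]))

    if cfg.run_selection:
        sel = run_stage("select", stage_select, state["observer"],
                        state["mesh_full"], state["domain"])
        spec = sel["spec"]
        report["stages"]["select"] = {
            "probability_terms": list(spec.probability_terms),
            "positive_terms": list(spec.positive_terms)}
    else:
        spec = ModelSpec(probability_terms=list(cfg.final_spec_z),
                         positive_terms=list(cfg.final_spec_y))
        report["skipped"].append("select")

    pred = run_stage("predict", stage_predict, state["observer"],
                     state["fleet"], state["mesh_full"], state["domain"],
                     spec)
    report["stages"]["predict"] = {
        "dic_z": pred["fit"].dic_z, "dic_y": pred["fit"].dic_y,
        "waic_z": pred["fit"].waic_z, "waic_y": pred["fit"].waic_y,
        "total_bycatch_mean": float(pred["tables"]["total"]["mean"][0]),
        "total_bycatch_cv": float(pred["tables"]["total"]["cv"][0]),
        "n_excluded_sets": pred["expect"].n_excluded}

    hs = run_stage("hotspot", stage_hotspot, state["observer"],
                   state["mesh_sub"], state["sub_domain"], state["climate"])
    sig = hs["ccf"][hs["ccf"]["significant"]]
    report["stages"]["hotspot"] = {
        "zero_bycatch_years": hs["zero_bycatch_years"],
        "significant_lags": sig["lag"].tolist()}

    if cfg.scenario_n_reps > 0:
        mit = run_stage("mitigate", stage_mitigate, state["fleet"],
                        state["domain"], pred["expect"], pred["draws"])
        best = mit["summary"][mit["summary"].metric == "pct_bycatch_change"]
        report["stages"]["mitigate"] = {
            "bycatch_change_by_scenario": {
                int(r.scenario): float(r.mean) for r in best.itertuples()},
            "n_aborted": {int(r.spec.id): r.n_aborted
                          for r in mit["results"]}}
    else:
        report["skipped"].append("mitigate")
        log.info("mitigation stage skipped (n_reps=0)")

    artifacts = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name not in
                       ("report.json", "run.log", "timings.json"))
    report["artifact_checksums"] = {
        str(p.relative_to(out)): _sha256(p) for p in artifacts}
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out / "timings.json", "w", encoding="utf-8") as fh:
        json.dump(timings, fh, indent=1)
    return report
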