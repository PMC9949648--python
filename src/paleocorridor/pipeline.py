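"""End-to-end scenario orchestration from one YAML config.

``run_scenario`` wires the whole chain — DEM + barrier scenario + sites →
slope → cost surface → least-cost routes → corridor reports (+ optional
climate-velocity map) — and writes a structured manifest.  Validation is
fail-fast: configuration errors (unknown site names, missing inputs) are
raised before any output is written, and identical configs over identical
inputs yield byte-identical outputs (the manifest carries input hashes, not
timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .barriers import BarrierScenario, build_scenario_mask
from .climate_velocity import ClimateEpochPair, climate_velocity, stability_mask
from .corridor import buffer_corridor, sites_in_corridor
from .cost_lcp import build_cost_surface, least_cost_path, write_path_geojson
from .exceptions import ConfigError
from .grid_io import read_grid, read_sites, write_grid, write_sites
from .terrain import compute_slope

log = logging.getLogger("paleocorridor")


@dataclass
class RouteSpec:
    start: str
    end: str
    apply_band: bool | None = None  # None -> scenario default


@dataclass
class RunConfig:
    dem: str
    sites: str
    scenario: str
    out_dir: str
    routes: list[RouteSpec] = field(default_factory=list)
    k_slope: float = 0.1
    buffer_km: float = 30.0
    t_old: str | None = None
    t_new: str | None = None
    delta_years: float = 110_000.0
    stability_quantile: float = 0.25
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            routes = [RouteSpec(r["start"], r["end"], r.get("apply_band"))
                      for r in doc.get("routes", [])]
            return cls(
                dem=doc["dem"], sites=doc["sites"], scenario=doc["scenario"],
                out_dir=doc["out_dir"], routes=routes,
                k_slope=float(doc.get("k_slope", 0.1)),
                buffer_km=float(doc.get("buffer_km", 30.0)),
                t_old=doc.get("t_old"), t_new=doc.get("t_new"),
                delta_years=float(doc.get("delta_years", 110_000.0)),
                stability_quantile=float(doc.get("stability_quantile", 0.25)),
                log_level=doc.get("log_level", "INFO"),
                seed=int(doc.get("seed", 0)),
            )
        except KeyError as err:
            raise ConfigError(f"config missing required key {err}") from err


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_scenario(config: RunConfig) -> dict:
    """Execute every route of a scenario; returns (and writes) the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    # ---- fail-fast validation, no outputs before this block passes -------
    inputs = {"dem": config.dem, "sites": config.sites, "scenario": config.scenario}
    if config.t_old:
        inputs["t_old"] = config.t_old
    if config.t_new:
        inputs["t_new"] = config.t_new
    for label, p in inputs.items():
        if not Path(p).exists():
            raise ConfigError(f"{label} input not found: {p}")
    dem = read_grid(config.dem, "ascii_grid")
    sites = read_sites(config.sites)
    scenario = BarrierScenario.from_yaml(config.scenario)
    known = set(sites.names())
    for route in config.routes:
        missing = {route.start, route.end} - known
        if missing:
            raise ConfigError(f"route names unknown sites {sorted(missing)}")
    if not config.routes:
        raise ConfigError("config defines no routes")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("stage=slope cells=%d", dem.values.size)
    slope = compute_slope(dem)

    manifest: dict = {
        "version": __version__,
        "scenario": scenario.name,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "config": {
            "k_slope": config.k_slope, "buffer_km": config.buffer_km,
            "delta_years": config.delta_years,
            "stability_quantile": config.stability_quantile, "seed": config.seed,
        },
        "routes": [],
        "outputs": {},
    }

    cost_cache: dict[bool, object] = {}
    for route in config.routes:
        apply_band = scenario.apply_band if route.apply_band is None else route.apply_band
        if apply_band not in cost_cache:
            from dataclasses import replace

            scen = replace(scenario, apply_band=apply_band)
            blocked = build_scenario_mask(dem, scen)
            cost_cache[apply_band] = build_cost_surface(
                slope, blocked, k_slope=config.k_slope, scenario_name=scen.name)
            log.info("stage=cost_surface apply_band=%s blocked=%d",
                     apply_band, int(cost_cache[apply_band].blocked.sum()))
        cost = cost_cache[apply_band]

        start = sites.get(route.start)
        end = sites.get(route.end)
        log.info("stage=lcp route=%s->%s", route.start, route.end)
        path = least_cost_path(
            cost, (float(start["lon"]), float(start["lat"])),
            (float(end["lon"]), float(end["lat"])),
            start_name=route.start, end_name=route.end)

        stem = f"route_{route.start}_{route.end}"
        path_file = out_dir / f"{stem}.geojson"
        write_path_geojson(path, path_file)
        corr = buffer_corridor(path, config.buffer_km)
        in_corr = sites_in_corridor(sites, corr)
        corr_file = out_dir / f"{stem}_corridor.csv"
        write_sites(in_corr, corr_file)
        log.info("stage=corridor route=%s->%s sites=%d",
                 route.start, route.end, len(in_corr))

        manifest["routes"].append({
            "start": route.start, "end": route.end, "apply_band": apply_band,
            "total_cost": path.total_cost, "length_km": path.length_km,
            "n_cells": len(path), "corridor_sites": in_corr.names(),
            "path_file": path_file.name, "corridor_file": corr_file.name,
        })

    if config.t_old and config.t_new:
        log.info("stage=velocity delta_years=%g", config.delta_years)
        pair = ClimateEpochPair(
            t_old=read_grid(config.t_old, "ascii_grid"),
            t_new=read_grid(config.t_new, "ascii_grid"),
            delta_years=config.delta_years)
        vel = climate_velocity(pair)
        stable = stability_mask(vel, config.stability_quantile)
        write_grid(vel, out_dir / "velocity.asc")
        write_grid(stable, out_dir / "refugia.asc")
        manifest["outputs"]["velocity"] = "velocity.asc"
        manifest["outputs"]["refugia"] = "refugia.asc"

    manifest_file = out_dir / "manifest.json"
    with open(manifest_file, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["outputs"]["manifest"] = manifest_file.name
    return manifest
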