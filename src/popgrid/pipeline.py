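"""Configuration-driven orchestration of the pipeline stages.

Stages run in dependency order (grid/simulate -> census -> covariates ->
dasymetric -> applications) against a working directory, writing a JSON
manifest with parameters, input digests and the per-unit conservation
audit.  Reruns with an identical configuration reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import census as census_mod
from . import io as pio
from .applications import (DEFAULT_MIN_EVENTS, DEFAULT_PREVALENCE_THRESHOLD,
                           DEFAULT_ZONE_KM, conflict_zones, population_at_risk,
                           population_near_conflict)
from .covariates_static import EarthModel, pixel_area_grid
from .dasymetric import (CovariateStack, fit_density_model,
                         predict_weight_surface, redistribute_counts,
                         zonal_covariate_summary)
from .grid import AdminIdRaster, GridRaster
from .synthetic import WorldConfig, simulate_world

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "census", "covariates", "dasymetric", "apps")


@dataclass
class PipelineConfig:
    """Everything a full run needs; every analysis constant is a named key."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    target_year: int = 2005
    prevalence_threshold: float = DEFAULT_PREVALENCE_THRESHOLD
    zone_km: float = DEFAULT_ZONE_KM
    min_events: int = DEFAULT_MIN_EVENTS
    world: dict = field(default_factory=dict)   # WorldConfig overrides

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if ("dasymetric" in self.stages or "simulate" in self.stages) \
                and self.seed is None:
            raise ValueError("a seed is required for stochastic stages")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        raw["out_dir"] = Path(raw.get("out_dir", "."))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": list(cfg.stages),
                      "parameters": {
                          "target_year": cfg.target_year,
                          "prevalence_threshold": cfg.prevalence_threshold,
                          "zone_km": cfg.zone_km,
                          "min_events": cfg.min_events,
                      },
                      "artefacts": {}, "timings_s": {}}
    if not cfg.stages:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    def record(name: str, path: Path) -> None:
        manifest["artefacts"][name] = {"path": str(path), "sha256": _digest(path)}

    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s starting", stage)

        if stage == "simulate":
            world = simulate_world(WorldConfig(seed=cfg.seed, **cfg.world))
            state["world"] = world
            pio.write_raster(out / "admin.tif", world.admin)
            pio.write_raster(out / "truth.tif", world.truth)
            pio.write_raster(out / "prevalence.tif", world.prevalence)
            census_mod.records_to_csv(world.census, out / "census.csv")
            for name, layer in world.stack.layers.items():
                pio.write_raster(out / f"cov_{name}.tif", layer)
            record("admin", out / "admin.tif")
            record("census", out / "census.csv")

        elif stage == "census":
            world = _need(state, "world", stage)
            series = [census_mod.interpolate_census_series(rec)
                      for rec in world.census]
            census_mod.series_to_csv(series, out / "census_annual.csv")
            state["counts"] = {s.unit_id: s.counts[cfg.target_year]
                               for s in series}
            record("census_annual", out / "census_annual.csv")

        elif stage == "covariates":
            world = _need(state, "world", stage)
            state["areas"] = pixel_area_grid(world.grid, EarthModel())
            pio.write_raster(out / "pixel_area.tif", state["areas"])
            record("pixel_area", out / "pixel_area.tif")

        elif stage == "dasymetric":
            world = _need(state, "world", stage)
            counts = _need(state, "counts", stage)
            areas = _need(state, "areas", stage)
            model_stack = CovariateStack({k: v for k, v in world.stack.layers.items()
                                          if k != "landcover"})
            summaries = zonal_covariate_summary(model_stack, world.admin, areas)
            model = fit_density_model(summaries, counts, seed=cfg.seed)
            land = GridRaster(world.grid,
                              np.ones(world.grid.shape, dtype=np.uint8),
                              "binary", nodata=255)
            weights = predict_weight_surface(model, model_stack, land)
            pop, audit = redistribute_counts(weights, world.admin, counts)
            state["population"] = pop
            pio.write_raster(out / "population.tif", pop)
            audit.to_csv(out / "conservation_audit.csv", index=False)
            manifest["conservation_violations"] = int(
                (audit["input_count"] != audit["output_sum"]).sum())
            record("population", out / "population.tif")
            record("conservation_audit", out / "conservation_audit.csv")

        elif stage == "apps":
            world = _need(state, "world", stage)
            pop = _need(state, "population", stage)
            risk = population_at_risk(pop, world.prevalence, world.admin,
                                      threshold=cfg.prevalence_threshold)
            risk.to_csv(out / "population_at_risk.csv", index=False)
            flagged = conflict_zones(world.events, world.grid,
                                     zone_km=cfg.zone_km,
                                     min_events=cfg.min_events)
            pio.write_raster(out / "conflict_zones.tif", flagged)
            near = population_near_conflict(pop, flagged, world.admin)
            near.to_csv(out / "population_near_conflict.csv", index=False)
            record("population_at_risk", out / "population_at_risk.csv")
            record("population_near_conflict", out / "population_near_conflict.csv")

        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, manifest["timings_s"][stage])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _need(state: dict, key: str, stage: str):
    if key not in state:
        raise ValueError(f"stage {stage!r} needs upstream artefact {key!r}; "
                         "enable the producing stage")
    return state[key]
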