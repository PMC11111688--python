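"""End-to-end pipeline driver: synthetic world → persistence → biomass → carbon.

A single YAML-serializable config governs a run. Every run writes its
resolved config and a provenance record (config hash, seed, package and
library versions) next to its outputs, and identical (config, seed) pairs
produce byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from . import befun, carbon as carbon_mod, synthetic
from .carbon import (CarbonLossTable, EnvelopeResult, broadcast_regions, carbon_delta,
                     mask_soils, total_carbon_loss, uncertainty_envelope)
from .grids import DataError, ParameterError, cell_areas
from .persistence import ExpL1Kernel, SARParams, persistence_pipeline

logger = logging.getLogger(__name__)


class WorldParams(BaseModel):
    n_lat: int = 24
    n_lon: int = 36
    n_ecoregions: int = 24
    n_env_dims: int = 2
    climate_shift: float = 1.25
    condition_loss: float = 0.25
    true_b: float = 0.26
    env_noise: float = 0.0
    biomass_noise: float = 0.0
    present_condition_loss: float = 0.0


class EnvelopeParams(BaseModel):
    enabled: bool = True
    grid_points: int = 5


class PipelineConfig(BaseModel):
    scenario_name: str = "scenario"
    seed: int = 0
    world: WorldParams = Field(default_factory=WorldParams)
    world_path: str | None = None  # read a previously written world instead of generating
    kernel_sigma: float = 1.0
    z: float = 0.25
    z_range: tuple[float, float] = (0.1, 0.65)
    b: float = 0.26
    b_ci: tuple[float, float] = (0.16, 0.37)
    include_soil: bool = False
    excluded_soils: tuple[str, ...] = ("Gleysols", "Histosols", "Cryosols")
    clip_gains: bool = False
    envelope: EnvelopeParams = Field(default_factory=EnvelopeParams)
    output_dir: str = "results/run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(self.model_dump_json()),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> tuple[CarbonLossTable, EnvelopeResult | None, dict]:
    """Execute every stage and write all outputs under ``config.output_dir``.

    Returns the central carbon-loss table, the (z, b) envelope (or None when
    disabled), and the provenance record. On stage failure, partial outputs
    written by this run are removed and a :class:`StageError` names the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, writer) -> Path:
        p = outdir / name
        writer(p)
        written.append(p)
        return p

    t0 = time.time()
    stage = "synthetic_world"
    try:
        if config.world_path:
            world = synthetic.read_world(config.world_path)
        else:
            world = synthetic.make_world(seed=config.seed, **config.world.model_dump())
        _emit("world.nc", lambda p: synthetic.write_world(world, str(p)))
        written.append(outdir / "world.nc.manifest.csv")
        logger.debug("stage %s done in %.3fs", stage, time.time() - t0)

        stage = "persistence"
        t0 = time.time()
        kernel = ExpL1Kernel(sigma=config.kernel_sigma)
        areas = cell_areas(world.grid)
        sar = SARParams(z=config.z, z_range=config.z_range)
        pres = persistence_pipeline(world.env_present, world.env_future,
                                    world.condition_future, areas, kernel,
                                    world.ecoregions, sar)
        lab = world.ecoregions.labels.ravel()
        rows = [{"region_id": rid, "n_cells": int((lab == rid).sum()),
                 "area_m2": float(areas.ravel()[lab == rid].sum()),
                 "p_region": pres.p_region[int(rid)]}
                for rid in world.ecoregions.region_ids]
        pers_df = pd.DataFrame(rows)
        _emit("persistence.csv", lambda p: pers_df.to_csv(p, index=False, float_format="%.12g"))
        logger.debug("stage %s done in %.3fs", stage, time.time() - t0)

        stage = "befun"
        t0 = time.time()
        bio_df = pers_df[["region_id", "p_region"]].copy()
        bio_df["p_biomass"] = befun.biomass_fraction(bio_df["p_region"].to_numpy(), config.b)
        bio_df["loss_percent"] = befun.loss_percent(bio_df["p_biomass"].to_numpy())
        _emit("biomass.csv", lambda p: bio_df.to_csv(p, index=False, float_format="%.12g"))
        logger.debug("stage %s done in %.3fs", stage, time.time() - t0)

        stage = "carbon"
        t0 = time.time()
        world.soil.excluded = frozenset(config.excluded_soils)
        stocks = world.carbon
        if config.include_soil and stocks.cSoil is not None:
            stocks = carbon_mod.CarbonStocks(
                cVeg=stocks.cVeg, cSoil=mask_soils(stocks.cSoil, world.soil))
        pb_region = dict(zip(bio_df["region_id"].astype(int), bio_df["p_biomass"]))
        pb_cells = broadcast_regions(pb_region, world.ecoregions, world.grid)
        delta = carbon_delta(stocks, pb_cells, include_soil=config.include_soil)
        table = total_carbon_loss(delta, areas, world.ecoregions,
                                  scenario=config.scenario_name, z=config.z, b=config.b,
                                  clip_gains=config.clip_gains)
        full = table.table.merge(bio_df[["region_id", "p_region", "p_biomass"]], on="region_id")
        full = full[["region_id", "area_m2", "p_region", "p_biomass", "dC_mean_kg_m2", "loss_PgC"]]
        _emit("carbon_by_ecoregion.csv", lambda p: full.to_csv(p, index=False, float_format="%.12g"))
        logger.debug("stage %s done in %.3fs", stage, time.time() - t0)

        stage = "envelope"
        t0 = time.time()
        env_res: EnvelopeResult | None = None
        if config.envelope.enabled:
            env_res = uncertainty_envelope(
                pres.area_ratio, pres.weights, world.ecoregions, stocks, areas,
                include_soil=config.include_soil, z_range=config.z_range,
                b_range=config.b_ci, grid_points=config.envelope.grid_points,
                z_central=config.z, b_central=config.b, scenario=config.scenario_name)
            _emit("envelope.csv",
                  lambda p: env_res.surface.to_csv(p, index=False, float_format="%.12g"))
        logger.debug("stage %s done in %.3fs", stage, time.time() - t0)

        stage = "report"
        provenance = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "biocarbon_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }
        summary = {
            "scenario": config.scenario_name,
            "z": config.z, "b": config.b,
            "include_soil": config.include_soil,
            "total_PgC": table.total_PgC,
            "n_ecoregions": int(len(table.table)),
            "skipped_area_m2": table.skipped_area_m2,
        }
        if env_res is not None:
            summary["envelope"] = {"min_PgC": env_res.vmin, "central_PgC": env_res.central,
                                   "max_PgC": env_res.vmax}
        _emit("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True)))
        _emit("provenance.json", lambda p: p.write_text(json.dumps(provenance, indent=2, sort_keys=True)))
        _emit("config.resolved.yaml", lambda p: config.to_yaml(p))
    except (ParameterError, DataError, OSError, RuntimeError, ValueError) as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    return table, env_res, provenance
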