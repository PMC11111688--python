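"""Carbon accounting: biomass fractions → ΔC rasters → ecoregion and global PgC.

The proportional remaining-biomass fraction for each ecoregion is applied to
carbon stock rasters (vegetation carbon cVeg, optionally soil carbon cSoil,
both kg C/m²):

    ΔC = S · (1 − p_biomass),  S = cVeg  or  cVeg + cSoil(masked)

and integrated over spherical cell areas to per-region and global totals,

    C_total [PgC] = 1e-12 · Σ_k ΔC_k · A_k.

Soil classes dominated by hydrology or permafrost rather than plant diversity
(Gleysols, Histosols, Cryosols) are excluded from the soil term. Uncertainty
in the species-area exponent z and the biomass exponent b is propagated by
re-running the persistence → biomass → carbon chain over a (z, b) grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import befun
from .grids import DataError, GridSpec, ParameterError, RasterField, cell_areas, resample  # noqa: F401
from .persistence import EcoregionPartition, ecoregion_persistence, persistence_sar

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_SOILS = frozenset({"Gleysols", "Histosols", "Cryosols"})
KG_TO_PG = 1.0e-12  # kg → Pg conversion in the global sum


@dataclass
class CarbonStocks:
    """Vegetation (cVeg) and optional soil (cSoil) carbon, kg C/m²."""

    cVeg: RasterField
    cSoil: RasterField | None = None

    def __post_init__(self) -> None:
        for f in (self.cVeg, self.cSoil):
            if f is None:
                continue
            v = f.values
            if np.any(v[~np.isnan(v)] < 0):
                raise DataError(f"carbon stock '{f.name}' has negative values")
        if self.cSoil is not None and self.cSoil.grid != self.cVeg.grid:
            raise DataError("cVeg and cSoil must share one grid; resample first")


@dataclass
class SoilClassField:
    """Integer-coded WRB soil classes with the set excluded from soil accounting."""

    classes: RasterField  # categorical codes
    class_names: dict[int, str]
    excluded: frozenset[str] = DEFAULT_EXCLUDED_SOILS

    def __post_init__(self) -> None:
        if not self.classes.categorical:
            raise DataError("soil class raster must be categorical")

    def excluded_mask(self) -> np.ndarray:
        """Boolean mask of cells whose class is in the excluded set."""
        excluded_codes = {c for c, n in self.class_names.items() if n in self.excluded}
        known = set(self.class_names)
        vals = self.classes.values
        mask = np.zeros(vals.shape, dtype=bool)
        for code in np.unique(vals[~np.isnan(vals)]).astype(int):
            if code not in known:
                warnings.warn(f"unknown soil class code {code}; treated as not excluded")
                logger.warning("unknown soil class code %s treated as not excluded", code)
                continue
            if code in excluded_codes:
                mask |= vals == code
        return mask


def mask_soils(cSoil: RasterField, soil: SoilClassField) -> RasterField:
    """Zero the soil-carbon contribution on excluded soil classes.

    Excluded cells keep their vegetation carbon; only the soil term is
    removed, so they are set to 0 (not missing).
    """
    if soil.classes.grid != cSoil.grid:
        raise DataError("soil classes not on the cSoil grid; resample (nearest) first")
    out = cSoil.values.copy()
    out[soil.excluded_mask()] = 0.0
    return cSoil.with_values(out, name=cSoil.name + "_masked")


def broadcast_regions(per_region: dict[int, float], partition: EcoregionPartition,
                      grid: GridSpec) -> np.ndarray:
    """Paint a per-ecoregion value onto the cells of each region (NaN elsewhere)."""
    lab = np.asarray(partition.labels, dtype=float)
    if lab.shape != grid.shape:
        raise DataError("partition labels not on the requested grid")
    out = np.full(grid.shape, np.nan)
    for rid, val in per_region.items():
        out[lab == rid] = val
    return out


def carbon_delta(stocks: CarbonStocks, p_biomass: np.ndarray,
                 include_soil: bool = False) -> RasterField:
    """Per-cell carbon loss ΔC = S · (1 − p_biomass), kg C/m².

    Biomass gains (p_biomass > 1) yield negative ΔC (a carbon gain).
    """
    p = np.asarray(p_biomass, dtype=float)
    if p.shape != stocks.cVeg.grid.shape:
        raise DataError("p_biomass not on the carbon grid")
    if np.any(p[~np.isnan(p)] < 0):
        raise ParameterError("p_biomass must be >= 0")
    stock = stocks.cVeg.values
    if include_soil:
        if stocks.cSoil is None:
            raise ParameterError("include_soil=True but no cSoil supplied")
        stock = stock + stocks.cSoil.values
    delta = stock * (1.0 - p)
    return RasterField(stocks.cVeg.grid, delta, name="dC", units="kg C m-2")


@dataclass
class CarbonLossTable:
    """Per-ecoregion and global carbon loss for one (scenario, z, b) setting."""

    table: pd.DataFrame  # region_id, n_cells, area_m2, dC_mean_kg_m2, loss_PgC
    total_PgC: float
    scenario: str = ""
    z: float = float("nan")
    b: float = float("nan")
    skipped_area_m2: float = 0.0


def total_carbon_loss(delta: RasterField, areas: np.ndarray,
                      partition: EcoregionPartition, scenario: str = "",
                      z: float = float("nan"), b: float = float("nan"),
                      clip_gains: bool = False) -> CarbonLossTable:
    """Integrate ΔC over cell areas per ecoregion and globally (PgC).

    Cells with missing ΔC are skipped and their area reported. With
    ``clip_gains`` negative per-cell ΔC (carbon gains) is floored at zero
    before summation; the default keeps gains, matching reported loss ranges
    that include negative values.
    """
    lab = np.asarray(partition.labels).ravel()
    d = delta.values.ravel()
    a = np.asarray(areas, dtype=float).ravel()
    if lab.shape != d.shape or a.shape != d.shape:
        raise DataError("delta, areas, and partition must be co-registered; resample first")
    if clip_gains:
        d = np.maximum(d, 0.0)
    ok = ~np.isnan(d)
    rows = []
    for rid in partition.region_ids:
        m = (lab == rid) & ok
        area = float(a[m].sum())
        loss_kg = float((d[m] * a[m]).sum())
        rows.append({
            "region_id": int(rid),
            "n_cells": int(m.sum()),
            "area_m2": area,
            "dC_mean_kg_m2": loss_kg / area if area > 0 else float("nan"),
            "loss_PgC": KG_TO_PG * loss_kg,
        })
    tab = pd.DataFrame(rows)
    skipped = float(a[~ok].sum())
    return CarbonLossTable(table=tab, total_PgC=float(tab["loss_PgC"].sum()),
                           scenario=scenario, z=z, b=b, skipped_area_m2=skipped)


@dataclass
class EnvelopeResult:
    """C_total over a (z, b) grid with its central estimate and extremes."""

    surface: pd.DataFrame  # columns z, b, total_PgC
    central: float
    z_central: float
    b_central: float
    vmin: float = dc_field(init=False)
    vmax: float = dc_field(init=False)

    def __post_init__(self) -> None:
        self.vmin = float(self.surface["total_PgC"].min())
        self.vmax = float(self.surface["total_PgC"].max())


def uncertainty_envelope(area_ratio: np.ndarray, weights: np.ndarray,
                         partition: EcoregionPartition, stocks: CarbonStocks,
                         areas: np.ndarray, include_soil: bool = False,
                         z_range: tuple[float, float] = (0.1, 0.65),
                         b_range: tuple[float, float] = (0.16, 0.37),
                         grid_points: int = 5,
                         z_central: float = 0.25, b_central: float = 0.26,
                         scenario: str = "") -> EnvelopeResult:
    """Sweep the persistence → biomass → carbon chain over a (z, b) grid.

    The effective-area ratio and aggregation weights do not depend on z or b,
    so they are computed once upstream and reused. The evaluated grid always
    contains the four corner combinations and the central pair.
    """
    if grid_points < 2:
        raise ParameterError("grid_points must be >= 2")
    if not (z_range[0] <= z_range[1]) or not (b_range[0] <= b_range[1]):
        raise ParameterError("z_range and b_range must be ordered")
    zs = np.union1d(np.linspace(*z_range, grid_points), [z_central])
    bs = np.union1d(np.linspace(*b_range, grid_points), [b_central])
    zs = zs[(zs >= min(z_range[0], z_central)) & (zs <= max(z_range[1], z_central))]
    bs = bs[(bs >= min(b_range[0], b_central)) & (bs <= max(b_range[1], b_central))]

    grid = stocks.cVeg.grid
    rows = []
    central = None
    for z in zs:
        p_cell = persistence_sar(area_ratio, float(z))
        p_region = ecoregion_persistence(p_cell, weights, partition)
        for b in bs:
            pb_region = {k: befun.biomass_fraction(v, float(b)) for k, v in p_region.items()}
            pb_cells = broadcast_regions(pb_region, partition, grid)
            delta = carbon_delta(stocks, pb_cells, include_soil=include_soil)
            res = total_carbon_loss(delta, areas, partition, scenario=scenario,
                                    z=float(z), b=float(b))
            rows.append({"z": float(z), "b": float(b), "total_PgC": res.total_PgC})
            if np.isclose(z, z_central) and np.isclose(b, b_central):
                central = res.total_PgC
    surface = pd.DataFrame(rows)
    if central is None:  # central pair outside the swept ranges
        p_cell = persistence_sar(area_ratio, z_central)
        p_region = ecoregion_persistence(p_cell, weights, partition)
        pb = {k: befun.biomass_fraction(v, b_central) for k, v in p_region.items()}
        delta = carbon_delta(stocks, broadcast_regions(pb, partition, grid), include_soil)
        central = total_carbon_loss(delta, areas, partition).total_PgC
    return EnvelopeResult(surface=surface, central=float(central),
                          z_central=z_central, b_central=b_central)


def scenario_compare(result_a: CarbonLossTable, result_b: CarbonLossTable) -> float:
    """Relative reduction of scenario a against scenario b, percent: (1 − a/b)·100."""
    if result_b.total_PgC == 0:
        raise ParameterError("comparison undefined: reference scenario total is zero")
    return (1.0 - result_a.total_PgC / result_b.total_PgC) * 100.0


def cumulative_loss_by_area(table: CarbonLossTable, p_region: dict[int, float],
                            species_loss_bins: np.ndarray) -> pd.DataFrame:
    """Cumulative carbon loss vs cumulative ecoregion area, by species-loss bin.

    Regions are grouped by proportional species loss (percent), then within
    each bin sorted by area ascending and accumulated — small regions first —
    giving the curves that show how many-but-moderate regions can outweigh
    few-but-severe ones.
    """
    edges = np.asarray(species_loss_bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterError("species_loss_bins must be increasing edges, length >= 2")
    df = table.table.copy()
    df["species_loss_pct"] = df["region_id"].map(
        {k: (1.0 - v) * 100.0 for k, v in p_region.items()})
    if df["species_loss_pct"].isna().any():
        raise DataError("p_region missing for some regions in the loss table")
    lo, hi = df["species_loss_pct"].min(), df["species_loss_pct"].max()
    if lo < edges[0] or hi > edges[-1]:
        raise ParameterError(
            f"bins [{edges[0]}, {edges[-1]}] do not cover observed losses [{lo:.3g}, {hi:.3g}]")
    df["bin"] = pd.cut(df["species_loss_pct"], edges, include_lowest=True)
    out = []
    for b, g in df.groupby("bin", observed=True):
        g = g.sort_values("area_m2", kind="mergesort")
        g = g.assign(cum_area_m2=g["area_m2"].cumsum(), cum_loss_PgC=g["loss_PgC"].cumsum())
        g["bin"] = str(b)
        out.append(g[["bin", "region_id", "area_m2", "loss_PgC",
                      "cum_area_m2", "cum_loss_PgC", "species_loss_pct"]])
    return pd.concat(out, ignore_index=True)
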