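import numpy as np
import pandas as pd
import pytest

from biocarbon import (CarbonLossTable, CarbonStocks, EcoregionPartition, GridSpec,
                       ParameterError, RasterField, SoilClassField, biomass_fraction,
                       broadcast_regions, carbon_delta, cell_areas, cumulative_loss_by_area,
                       mask_soils, scenario_compare, total_carbon_loss, uncertainty_envelope)
from biocarbon.carbon import DEFAULT_EXCLUDED_SOILS
from biocarbon.grids import DataError
from biocarbon.synthetic import SOIL_CLASS_NAMES


def _soil_field(grid, codes):
    return SoilClassField(
        classes=RasterField(grid, np.asarray(codes, float), categorical=True),
        class_names=dict(SOIL_CLASS_NAMES))


class TestMaskSoils:
    def test_excluded_classes_zeroed_others_kept(self):
        g = GridSpec(1, 4)
        csoil = RasterField(g, np.array([[10.0, 20.0, 30.0, 40.0]]), name="cSoil")
        # Cambisols, Gleysols, Histosols, Cryosols
        soil = _soil_field(g, [[0, 3, 4, 5]])
        out = mask_soils(csoil, soil)
        assert np.allclose(out.values, [[10.0, 0.0, 0.0, 0.0]])

    def test_all_excluded_removes_soil_term_entirely(self):
        g = GridSpec(2, 2)
        csoil = RasterField(g, np.full((2, 2), 9.0), name="cSoil")
        soil = _soil_field(g, np.full((2, 2), 4))  # Histosols everywhere
        masked = mask_soils(csoil, soil)
        stocks = CarbonStocks(cVeg=RasterField(g, np.full((2, 2), 5.0)), cSoil=masked)
        delta = carbon_delta(stocks, np.full((2, 2), 0.9), include_soil=True)
        assert np.allclose(delta.values, 5.0 * 0.1)  # only vegetation contributes

    def test_unknown_class_warned_and_not_excluded(self):
        g = GridSpec(1, 2)
        csoil = RasterField(g, np.array([[3.0, 3.0]]), name="cSoil")
        soil = _soil_field(g, [[0, 99]])
        with pytest.warns(UserWarning, match="unknown soil class"):
            out = mask_soils(csoil, soil)
        assert np.allclose(out.values, 3.0)

    def test_default_excluded_set(self):
        assert DEFAULT_EXCLUDED_SOILS == {"Gleysols", "Histosols", "Cryosols"}


class TestCarbonDelta:
    def test_no_biomass_change_means_no_loss(self):
        g = GridSpec(2, 3)
        stocks = CarbonStocks(cVeg=RasterField(g, np.random.default_rng(0).uniform(0, 9, (2, 3))))
        delta = carbon_delta(stocks, np.ones((2, 3)))
        assert np.allclose(delta.values, 0.0)

    def test_vegetation_only_arithmetic(self):
        g = GridSpec(1, 1)
        stocks = CarbonStocks(cVeg=RasterField(g, np.array([[10.0]])))
        delta = carbon_delta(stocks, np.array([[0.9]]))
        assert delta.values[0, 0] == pytest.approx(1.0)

    def test_with_soil_arithmetic(self):
        g = GridSpec(1, 1)
        stocks = CarbonStocks(cVeg=RasterField(g, np.array([[10.0]])),
                              cSoil=RasterField(g, np.array([[30.0]])))
        delta = carbon_delta(stocks, np.array([[0.95]]), include_soil=True)
        assert delta.values[0, 0] == pytest.approx(2.0)

    def test_gain_yields_negative_delta(self):
        g = GridSpec(1, 1)
        stocks = CarbonStocks(cVeg=RasterField(g, np.array([[10.0]])))
        assert carbon_delta(stocks, np.array([[1.1]])).values[0, 0] == pytest.approx(-1.0)

    def test_soil_requested_but_missing_rejected(self):
        g = GridSpec(1, 1)
        stocks = CarbonStocks(cVeg=RasterField(g, np.array([[10.0]])))
        with pytest.raises(ParameterError):
            carbon_delta(stocks, np.array([[0.9]]), include_soil=True)

    def test_soil_inclusion_never_shrinks_loss(self):
        g = GridSpec(4, 4)
        rng = np.random.default_rng(1)
        stocks = CarbonStocks(cVeg=RasterField(g, rng.uniform(1, 9, (4, 4))),
                              cSoil=RasterField(g, rng.uniform(1, 9, (4, 4))))
        p = rng.uniform(0.5, 1.5, (4, 4))
        d_veg = carbon_delta(stocks, p).values
        d_all = carbon_delta(stocks, p, include_soil=True).values
        assert np.all(np.abs(d_all) >= np.abs(d_veg) - 1e-12)


class TestTotalCarbonLoss:
    def test_unit_conversion_kg_to_pg(self):
        g = GridSpec(1, 1)
        delta = RasterField(g, np.array([[1.0]]))
        table = total_carbon_loss(delta, np.array([[1.0e12]]),
                                  EcoregionPartition(np.array([[0]])))
        assert table.total_PgC == pytest.approx(1.0)

    def test_zero_delta_gives_zero(self):
        g = GridSpec(3, 3)
        table = total_carbon_loss(RasterField(g, np.zeros((3, 3))), cell_areas(g),
                                  EcoregionPartition(np.zeros((3, 3), dtype=int)))
        assert table.total_PgC == 0.0

    def test_matches_brute_force_cell_sum(self):
        rng = np.random.default_rng(2)
        g = GridSpec(10, 10)
        delta = rng.normal(size=(10, 10))
        areas = cell_areas(g)
        labels = rng.integers(0, 7, size=(10, 10))
        table = total_carbon_loss(RasterField(g, delta), areas, EcoregionPartition(labels))
        brute = 0.0
        for i in range(10):
            for j in range(10):
                brute += 1e-12 * delta[i, j] * areas[i, j]
        assert table.total_PgC == pytest.approx(brute, rel=1e-12)
        assert table.total_PgC == pytest.approx(table.table["loss_PgC"].sum(), rel=1e-12)

    def test_missing_cells_skipped_and_area_reported(self):
        g = GridSpec(1, 2)
        delta = RasterField(g, np.array([[1.0, np.nan]]))
        areas = np.array([[2.0e12, 3.0e12]])
        table = total_carbon_loss(delta, areas, EcoregionPartition(np.array([[0, 0]])))
        assert table.total_PgC == pytest.approx(2.0)
        assert table.skipped_area_m2 == pytest.approx(3.0e12)

    def test_clip_gains_floors_negative_cells(self):
        g = GridSpec(1, 2)
        delta = RasterField(g, np.array([[1.0, -1.0]]))
        areas = np.array([[1.0e12, 1.0e12]])
        part = EcoregionPartition(np.array([[0, 0]]))
        assert total_carbon_loss(delta, areas, part).total_PgC == pytest.approx(0.0)
        assert total_carbon_loss(delta, areas, part, clip_gains=True).total_PgC \
            == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        g = GridSpec(2, 2)
        delta = RasterField(g, np.zeros((2, 2)))
        with pytest.raises(DataError):
            total_carbon_loss(delta, np.ones((3, 3)), EcoregionPartition(np.zeros((2, 2), int)))


def _loss_only_setup():
    """A small world-like setup where every region loses species (ratio < 1)."""
    g = GridSpec(6, 8)
    rng = np.random.default_rng(7)
    ratio = rng.uniform(0.4, 0.95, size=g.n_cells)
    weights = rng.uniform(0.5, 2.0, size=g.n_cells)
    part = EcoregionPartition(rng.integers(0, 5, size=g.shape))
    stocks = CarbonStocks(cVeg=RasterField(g, rng.uniform(1, 10, g.shape)))
    return ratio, weights, part, stocks, cell_areas(g)


class TestEnvelope:
    def test_degenerate_ranges_collapse(self):
        ratio, w, part, stocks, areas = _loss_only_setup()
        env = uncertainty_envelope(ratio, w, part, stocks, areas,
                                   z_range=(0.25, 0.25), b_range=(0.26, 0.26))
        assert env.vmin == pytest.approx(env.central, rel=1e-12)
        assert env.vmax == pytest.approx(env.central, rel=1e-12)

    def test_central_contained_and_corners_extremal_for_loss_only(self):
        ratio, w, part, stocks, areas = _loss_only_setup()
        env = uncertainty_envelope(ratio, w, part, stocks, areas)
        assert env.vmin <= env.central <= env.vmax
        s = env.surface
        lo = s[(s.z == s.z.min()) & (s.b == s.b.min())]["total_PgC"].iloc[0]
        hi = s[(s.z == s.z.max()) & (s.b == s.b.max())]["total_PgC"].iloc[0]
        assert lo == pytest.approx(env.vmin, rel=1e-12)
        assert hi == pytest.approx(env.vmax, rel=1e-12)

    def test_surface_monotone_in_b_along_every_z_slice(self):
        ratio, w, part, stocks, areas = _loss_only_setup()
        env = uncertainty_envelope(ratio, w, part, stocks, areas)
        for _, grp in env.surface.groupby("z"):
            vals = grp.sort_values("b")["total_PgC"].to_numpy()
            assert np.all(np.diff(vals) > 0)


class TestScenarioCompare:
    def _table(self, total):
        return CarbonLossTable(table=pd.DataFrame({"loss_PgC": [total]}), total_PgC=total)

    def test_reported_totals_give_about_thirty_percent(self):
        red = scenario_compare(self._table(29.55), self._table(42.89))
        assert red == pytest.approx(31.1, abs=0.05)

    def test_equal_totals_zero(self):
        assert scenario_compare(self._table(5.0), self._table(5.0)) == pytest.approx(0.0)

    def test_zero_numerator_full_reduction(self):
        assert scenario_compare(self._table(0.0), self._table(5.0)) == pytest.approx(100.0)

    def test_zero_reference_flagged(self):
        with pytest.raises(ParameterError):
            scenario_compare(self._table(1.0), self._table(0.0))


class TestCumulativeLossByArea:
    def _table_from(self, areas, losses, p_region):
        df = pd.DataFrame({
            "region_id": np.arange(len(areas)),
            "n_cells": 1,
            "area_m2": areas,
            "dC_mean_kg_m2": np.array(losses) / np.array(areas) * 1e12,
            "loss_PgC": losses,
        })
        return CarbonLossTable(table=df, total_PgC=float(np.sum(losses))), p_region

    def test_single_region_single_point(self):
        table, p = self._table_from([1e12], [2.0], {0: 0.9})
        out = cumulative_loss_by_area(table, p, np.array([0.0, 50.0]))
        assert len(out) == 1
        assert out["cum_area_m2"].iloc[0] == pytest.approx(1e12)
        assert out["cum_loss_PgC"].iloc[0] == pytest.approx(2.0)

    def test_bin_totals_conserve_global_total(self):
        rng = np.random.default_rng(3)
        n = 12
        areas = rng.uniform(1e11, 1e13, n)
        losses = rng.uniform(0, 3, n)
        p = {i: rng.uniform(0.55, 0.99) for i in range(n)}
        table, p = self._table_from(areas, losses, p)
        out = cumulative_loss_by_area(table, p, np.array([0.0, 10.0, 20.0, 30.0, 50.0]))
        final = out.groupby("bin", observed=True)["cum_loss_PgC"].last().sum()
        assert final == pytest.approx(table.total_PgC, rel=1e-9)

    def test_populous_moderate_bin_outweighs_small_severe_bin(self):
        # many large mid-loss regions vs one small high-loss region
        areas = [5e12] * 6 + [1e11]
        losses = [5e12 * 0.5 * 1e-12] * 6 + [1e11 * 2.0 * 1e-12]
        p = {i: 0.85 for i in range(6)} | {6: 0.6}  # 15% vs 40% species loss
        table, p = self._table_from(areas, losses, p)
        out = cumulative_loss_by_area(table, p, np.array([0.0, 20.0, 50.0]))
        by_bin = out.groupby("bin", observed=True)["cum_loss_PgC"].last()
        mid = [b for b in by_bin.index if b.endswith("20.0]")][0]
        high = [b for b in by_bin.index if b.endswith("50.0]")][0]
        assert by_bin[mid] > by_bin[high]

    def test_within_bin_sorted_by_area_ascending(self):
        table, p = self._table_from([3e12, 1e12, 2e12], [1.0, 1.0, 1.0],
                                    {0: 0.9, 1: 0.9, 2: 0.9})
        out = cumulative_loss_by_area(table, p, np.array([0.0, 50.0]))
        assert list(out["area_m2"]) == [1e12, 2e12, 3e12]

    def test_uncovered_losses_rejected(self):
        table, p = self._table_from([1e12], [1.0], {0: 0.2})  # 80% loss
        with pytest.raises(ParameterError):
            cumulative_loss_by_area(table, p, np.array([0.0, 50.0]))


class TestBroadcastRegions:
    def test_paints_each_region_and_leaves_gaps_nan(self):
        g = GridSpec(2, 2)
        part = EcoregionPartition(np.array([[0, 0], [1, 2]]))
        out = broadcast_regions({0: 0.5, 1: 0.8}, part, g)
        assert out[0, 0] == 0.5 and out[0, 1] == 0.5 and out[1, 0] == 0.8
        assert np.isnan(out[1, 1])  # region 2 not supplied


class TestStocksValidation:
    def test_negative_stock_rejected(self):
        g = GridSpec(1, 1)
        with pytest.raises(DataError):
            CarbonStocks(cVeg=RasterField(g, np.array([[-1.0]])))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(DataError):
            CarbonStocks(cVeg=RasterField(GridSpec(1, 1), np.array([[1.0]])),
                         cSoil=RasterField(GridSpec(2, 2), np.ones((2, 2))))


def test_biomass_fraction_feeds_delta_consistently():
    """p_region -> p_biomass -> dC agrees with direct closed-form composition."""
    g = GridSpec(1, 1)
    stocks = CarbonStocks(cVeg=RasterField(g, np.array([[10.0]])))
    p_region = 0.84
    pb = biomass_fraction(p_region, 0.26)
    delta = carbon_delta(stocks, np.array([[pb]]))
    assert delta.values[0, 0] == pytest.approx(10.0 * (1 - 0.84 ** 0.26), rel=1e-12)
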