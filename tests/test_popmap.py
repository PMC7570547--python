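import numpy as np
import pytest
from shapely.geometry import box

import oracles
from rnahsi.grid import Grid, GridSpec
from rnahsi.popmap import (
    correction_factor,
    disaggregate,
    fit_linear_calibration,
    to_density,
    zonal_sum,
)
from rnahsi.vectors import Zone, ZoneSet

CRS = "EPSG:32650"


class TestZonalSum:
    def test_single_zone_equals_grid_total(self, small_spec, rng):
        g = Grid(rng.uniform(0, 5, (10, 10)), small_spec)
        zones = ZoneSet([Zone("all", box(0, 0, 1000, 1000), 10)], crs=CRS)
        sums = zonal_sum(g, zones)
        assert sums["all"] == pytest.approx(g.values.sum(), rel=1e-12)

    def test_constant_grid_counts_cells(self, small_spec, quad_zones):
        g = Grid(np.full((10, 10), 3.0), small_spec)
        sums = zonal_sum(g, quad_zones)
        # each quadrant zone covers 25 cell centres
        np.testing.assert_allclose(sums.to_numpy(), [75.0] * 4)

    def test_matches_point_in_polygon_oracle(self, rng):
        spec = GridSpec((20, 20), (0.0, 2000.0), 100.0, CRS)
        v = rng.uniform(0, 9, (20, 20))
        zones = ZoneSet(
            [
                Zone("p", box(0, 1100, 700, 2000), 1),
                Zone("q", box(700, 1100, 2000, 2000), 1),
                Zone("r", box(0, 0, 1300, 1100), 1),
                Zone("s", box(1300, 0, 2000, 1100), 1),
            ],
            crs=CRS,
        )
        got = zonal_sum(Grid(v, spec), zones).to_numpy()
        want = oracles.zonal_sums_point_in_polygon(v, spec, zones)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_partition_sums_to_grid_total(self, small_spec, quad_zones, rng):
        g = Grid(rng.uniform(0, 2, (10, 10)), small_spec)
        sums = zonal_sum(g, quad_zones)
        assert sums.sum() == pytest.approx(g.values.sum(), rel=1e-12)

    def test_empty_zone_warns_and_is_zero(self, small_spec, caplog):
        zones = ZoneSet(
            [
                Zone("big", box(0, 0, 1000, 1000), 5),
                Zone("sliver", box(1000, 0, 1001, 1), 5),
            ],
            crs=CRS,
        )
        g = Grid(np.ones((10, 10)), small_spec)
        with caplog.at_level("WARNING"):
            sums = zonal_sum(g, zones)
        assert sums["sliver"] == 0.0
        assert "sliver" in caplog.text


class TestLinearCalibration:
    def test_exact_line(self):
        fit = fit_linear_calibration([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_population(self):
        fit = fit_linear_calibration([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 100, 10)
        y = 3.1 * x + 40 + rng.normal(0, 5, 10)
        fit = fit_linear_calibration(x, y)
        slope, intercept = oracles.ols_normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_linear_calibration([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrectionFactor:
    @pytest.mark.parametrize(
        "est,act,expected", [(100.0, 100.0, 1.0), (100.0, 82.0, 0.82), (400.0, 500.0, 1.25)]
    )
    def test_ratio(self, est, act, expected):
        assert correction_factor(est, act) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_estimate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            correction_factor(0.0, 10.0)


class TestDisaggregate:
    def make(self, values, pops=(100,)):
        values = np.asarray(values, dtype=float)
        spec = GridSpec(values.shape, (0.0, values.shape[0] * 100.0), 100.0, CRS)
        rows, cols = values.shape
        if len(pops) == 1:
            zones = [Zone("z0", box(0, 0, cols * 100, rows * 100), pops[0])]
        else:  # vertical strips
            edges = np.linspace(0, cols * 100, len(pops) + 1)
            zones = [
                Zone(f"z{i}", box(edges[i], 0, edges[i + 1], rows * 100), p)
                for i, p in enumerate(pops)
            ]
        return Grid(values, spec), ZoneSet(zones, crs=CRS)

    def test_uniform_index_splits_evenly(self):
        g, zones = self.make([[1.0, 1.0], [1.0, 1.0]], (100,))
        out = disaggregate(g, zones, mode="proportional")
        np.testing.assert_allclose(out.values, 25.0)

    def test_proportional_hand_values(self):
        g, zones = self.make([[1.0, 3.0]], (80,))
        out = disaggregate(g, zones, mode="proportional")
        np.testing.assert_allclose(out.values, [[20.0, 60.0]])

    @pytest.mark.parametrize("mode", ["regression", "proportional", "proportional_by_zone"])
    def test_conservation_every_mode(self, rng, mode):
        v = rng.uniform(0, 2, (12, 12))
        g, zones = self.make(v, (400, 300, 250))
        fit = fit_linear_calibration(
            zonal_sum(g, zones).to_numpy(), zones.populations
        )
        out = disaggregate(g, zones, fit=fit, mode=mode)
        assert out.values.sum() == pytest.approx(950.0, rel=1e-9)

    def test_by_zone_conserves_each_zone(self, rng):
        v = rng.uniform(0, 2, (10, 10))
        g, zones = self.make(v, (123, 456))
        out = disaggregate(g, zones, mode="proportional_by_zone")
        per_zone = zonal_sum(out, zones)
        assert per_zone["z0"] == pytest.approx(123.0, rel=1e-9)
        assert per_zone["z1"] == pytest.approx(456.0, rel=1e-9)

    def test_invariant_to_index_rescaling(self, rng):
        v = rng.uniform(0.1, 2, (8, 8))
        g, zones = self.make(v, (500, 200))
        a = disaggregate(g, zones, mode="proportional").values
        b = disaggregate(g.with_values(37.5 * v), zones, mode="proportional").values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_zero_index_zone_spreads_uniformly(self, caplog):
        v = np.array([[0.0, 0.0, 1.0, 3.0]])
        g, zones = self.make(v, (50, 80))
        with caplog.at_level("WARNING"):
            out = disaggregate(g, zones, mode="proportional_by_zone")
        np.testing.assert_allclose(out.values, [[25.0, 25.0, 20.0, 60.0]])
        assert "z0" in caplog.text

    def test_regression_clips_negatives(self):
        v = np.array([[0.0, 0.0, 1.0, 5.0]])
        g, zones = self.make(v, (100,))
        # steep fit with negative intercept drives low cells negative
        fit = type(fit_linear_calibration([1, 2, 3], [1, 2, 3]))(50.0, -40.0, 0.9)
        out = disaggregate(g, zones, fit=fit, mode="regression")
        assert (out.values >= 0).all()
        assert out.values.sum() == pytest.approx(100.0, rel=1e-9)

    def test_unknown_mode_lists_valid(self):
        g, zones = self.make([[1.0]], (10,))
        with pytest.raises(ValueError, match="proportional_by_zone"):
            disaggregate(g, zones, mode="nearest")


class TestToDensity:
    @pytest.mark.parametrize(
        "cell,pop,expected",
        [(100.0, 37.0, 37.0), (200.0, 40.0, 10.0), (100.0, 0.0, 0.0)],
    )
    def test_unit_conversion(self, cell, pop, expected):
        spec = GridSpec((1, 1), (0.0, cell), cell, CRS)
        out = to_density(Grid(np.array([[pop]]), spec))
        assert out.values[0, 0] == pytest.approx(expected, rel=1e-12)
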