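import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box

import oracles
from rnahsi.grid import Grid, GridSpec
from rnahsi.kde import (
    ClassWeights,
    bandwidth_sweep,
    composite_rnd,
    line_kde,
    pca_class_weights,
)
from rnahsi.vectors import RoadFeature, RoadNetwork, Zone, ZoneSet

CRS = "EPSG:32650"


def net_of(segments, classes=None, crs=CRS):
    classes = classes or ["trunk"] * len(segments)
    return RoadNetwork(
        [RoadFeature(LineString(s), c) for s, c in zip(segments, classes)], crs=crs
    )


class TestLineKde:
    def test_empty_network_is_zero(self, small_spec):
        g = line_kde(net_of([]), "trunk", 500.0, small_spec)
        assert (g.values == 0).all()

    def test_missing_class_warns_and_zeroes(self, small_spec, caplog):
        net = net_of([[(0, 0), (100, 0)]], ["other"])
        with caplog.at_level("WARNING"):
            g = line_kde(net, "railway", 500.0, small_spec)
        assert (g.values == 0).all()
        assert "railway" in caplog.text

    def test_compact_support(self, small_spec):
        # 10 m segment near the origin corner; far cells must be exactly 0
        net = net_of([[(10, 990), (20, 990)]])
        g = line_kde(net, "trunk", 300.0, small_spec)
        X, Y = small_spec.center_mesh()
        far = np.hypot(X - 15, Y - 990) > 300.0 + 10.0
        assert (g.values[far] == 0).all()
        assert g.values[0, 0] > 0

    def test_densities_non_negative(self, small_spec, rng):
        segs = [rng.uniform(0, 1000, (3, 2)) for _ in range(4)]
        g = line_kde(net_of(segs), "trunk", 400.0, small_spec)
        assert (g.values >= 0).all()

    def test_matches_quadrature_oracle(self):
        spec = GridSpec((20, 20), (0.0, 2000.0), 100.0, CRS)
        segs = [
            [(300.0, 400.0), (1500.0, 1100.0)],
            [(200.0, 1700.0), (900.0, 1700.0), (900.0, 800.0)],
        ]
        h = 500.0
        impl = line_kde(net_of(segs), "trunk", h, spec, spacing=h / 5000.0)
        ref = oracles.line_kde_quadrature(
            [np.asarray(s) for s in segs], h, 100.0, (0.0, 2000.0), (20, 20)
        )
        np.testing.assert_allclose(impl.values, ref, rtol=1e-6, atol=1e-6 * ref.max())

    def test_additive_over_features(self, small_spec):
        a = [(100.0, 100.0), (800.0, 200.0)]
        b = [(200.0, 900.0), (700.0, 600.0)]
        both = line_kde(net_of([a, b]), "trunk", 400.0, small_spec)
        ga = line_kde(net_of([a]), "trunk", 400.0, small_spec)
        gb = line_kde(net_of([b]), "trunk", 400.0, small_spec)
        # equal up to float summation order
        np.testing.assert_allclose(both.values, ga.values + gb.values, rtol=1e-12)

    def test_mass_conservation_interior_network(self):
        # network > h from every edge: sum(density * area) ~ total length
        spec = GridSpec((40, 40), (0.0, 4000.0), 100.0, CRS)
        segs = [
            [(1200.0, 1300.0), (2800.0, 1500.0)],
            [(1500.0, 2500.0), (2500.0, 2600.0), (2600.0, 1800.0)],
        ]
        net = net_of(segs)
        g = line_kde(net, "trunk", 500.0, spec)
        mass = g.values.sum() * spec.cell_area_m2
        assert mass == pytest.approx(net.total_length(), rel=0.01)

    def test_crs_mismatch_rejected(self, small_spec):
        net = net_of([[(0, 0), (100, 0)]], crs="EPSG:32651")
        with pytest.raises(ValueError, match="CRS"):
            line_kde(net, "trunk", 500.0, small_spec)


class TestBandwidthSweep:
    def make_zones(self, pops):
        zones = [
            Zone(f"z{i}", box(i * 200, 0, (i + 1) * 200, 1000), p)
            for i, p in enumerate(pops)
        ]
        return ZoneSet(zones, crs=CRS)

    def test_perfect_proportionality_gives_r_one(self, small_spec):
        # one vertical road per zone, lengths proportional to population
        pops = [100, 200, 300, 400, 500]
        segs, classes = [], []
        for i, p in enumerate(pops):
            x = i * 200 + 100.0
            segs.append([(x, 500 - p / 2), (x, 500 + p / 2)])
            classes.append("trunk")
        net = net_of(segs, classes)
        sweep = bandwidth_sweep(
            net, self.make_zones(pops), [100.0, 200.0], small_spec, method="direct"
        )
        # KDE mass leaks between adjacent zones, so r is near but not exactly 1
        assert (sweep.table["r"] > 0.97).all()

    def test_pearson_matches_textbook_oracle(self, small_spec):
        rng = np.random.default_rng(3)
        pops = [120, 80, 260, 190, 330]
        segs = [
            [(i * 200 + 50.0, 200.0 + 80.0 * rng.uniform()), (i * 200 + 150.0, 800.0)]
            for i in range(5)
        ]
        net = net_of(segs)
        zones = self.make_zones(pops)
        sweep = bandwidth_sweep(net, zones, [100.0, 300.0], small_spec, method="direct")
        from rnahsi.kde import zonal_class_sums

        for h in (100.0, 300.0):
            sums = zonal_class_sums(net, zones, h, small_spec)["trunk"].to_numpy()
            want = oracles.pearson_r(sums, pops)
            got = sweep.table.query("bandwidth == @h")["r"].iloc[0]
            assert got == pytest.approx(want, abs=1e-12)

    def test_default_bandwidth_chosen(self, small_spec):
        net = net_of([[(100, 100), (900, 900)]])
        zones = self.make_zones([10, 20, 30, 40, 50])
        sweep = bandwidth_sweep(
            net, zones, [100.0, 200.0, 300.0], small_spec, default_bandwidth=300.0
        )
        assert sweep.chosen == 300.0

    def test_too_few_zones_rejected(self, small_spec):
        net = net_of([[(0, 0), (100, 0)]])
        with pytest.raises(ValueError, match="3 zones"):
            bandwidth_sweep(net, self.make_zones([5, 5]), [100.0, 200.0], small_spec)


class TestPcaClassWeights:
    def test_two_correlated_classes_split_evenly(self):
        x = np.linspace(1, 10, 12)
        df = pd.DataFrame({"trunk": x, "other": 3 * x + 1})
        w = pca_class_weights(df)
        assert w.weights["trunk"] == pytest.approx(0.5, abs=1e-12)
        assert w.weights["other"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_independent_eigensolver(self, rng):
        X = rng.uniform(1, 9, (10, 3))
        df = pd.DataFrame(X, columns=["expressway", "trunk", "other"])
        w = pca_class_weights(df)
        want = oracles.pca_weights_eig(X)
        got = np.array([w.weights[c] for c in df.columns])
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_invariant_to_column_rescaling(self, rng):
        X = rng.uniform(1, 9, (12, 4))
        cols = ["expressway", "trunk", "branch", "other"]
        w1 = pca_class_weights(pd.DataFrame(X, columns=cols))
        w2 = pca_class_weights(pd.DataFrame(X * [10, 0.1, 7, 1000], columns=cols))
        for c in cols:
            assert w1.weights[c] == pytest.approx(w2.weights[c], abs=1e-9)

    def test_equivariant_to_column_order(self, rng):
        X = rng.uniform(1, 9, (12, 3))
        cols = ["expressway", "trunk", "other"]
        w1 = pca_class_weights(pd.DataFrame(X, columns=cols))
        w2 = pca_class_weights(pd.DataFrame(X[:, ::-1], columns=cols[::-1]))
        for c in cols:
            assert w1.weights[c] == pytest.approx(w2.weights[c], abs=1e-9)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"trunk": [1.0, 2, 3, 4], "railway": [5.0, 5, 5, 5]})
        with pytest.raises(ValueError, match="railway"):
            pca_class_weights(df)

    def test_weights_sum_to_one(self, rng):
        X = rng.uniform(0.5, 5, (20, 6))
        from rnahsi.vectors import ROAD_CLASSES

        w = pca_class_weights(pd.DataFrame(X, columns=list(ROAD_CLASSES)))
        assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in w.weights.values())


class TestCompositeRnd:
    def test_single_class_identity(self, small_spec, rng):
        g = Grid(rng.uniform(0, 1, (10, 10)), small_spec)
        out = composite_rnd({"trunk": g}, ClassWeights({"trunk": 1.0}, [1.0]))
        np.testing.assert_array_equal(out.values, g.values)

    def test_half_half_is_mean(self, small_spec, rng):
        a = Grid(rng.uniform(0, 1, (10, 10)), small_spec)
        b = Grid(rng.uniform(0, 1, (10, 10)), small_spec)
        out = composite_rnd(
            {"trunk": a, "other": b}, ClassWeights({"trunk": 0.5, "other": 0.5}, [1.0])
        )
        np.testing.assert_allclose(out.values, (a.values + b.values) / 2)

    def test_six_class_overlay_with_published_weights(self, small_spec, rng):
        # weights printed for the six classes in the original study (sum 0.99)
        weights = {
            "expressway": 0.2,
            "trunk": 0.15,
            "secondary_trunk": 0.08,
            "branch": 0.15,
            "railway": 0.21,
            "other": 0.2,
        }
        grids = {c: Grid(rng.uniform(0, 2, (10, 10)), small_spec) for c in weights}
        out = composite_rnd(grids, weights)
        # spot-check cells by hand-style arithmetic
        for i, j in [(0, 0), (3, 7), (9, 9)]:
            want = sum(weights[c] * grids[c].values[i, j] for c in weights)
            assert out.values[i, j] == pytest.approx(want, rel=1e-12)

    def test_class_weight_mismatch_rejected(self, small_spec):
        g = Grid(np.zeros((10, 10)), small_spec)
        with pytest.raises(ValueError, match="mismatch"):
            composite_rnd({"trunk": g}, ClassWeights({"other": 1.0}, [1.0]))
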