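"""Indicator derivation: matching rules, statistics, NaN semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from coastnest.indicators import (
    MatchRule,
    NodeSeriesSet,
    circular_std_deg,
    compute_madm,
    current_proximity,
    derive_geophysical,
    derive_node_indicators,
    habitat_distance,
    match_nodes,
    series_stats,
    tidal_range_per_node,
)
from coastnest.geodesy import destination_point, haversine_km
from coastnest.registry import CLASS_INDICATORS, INDICATOR_COLUMNS


def nodes_at_distances(clc, distances_km, bearing=90.0):
    lons, lats = [], []
    for d in distances_km:
        lon, lat = destination_point(clc[0], clc[1], bearing, d)
        lons.append(lon)
        lats.append(lat)
    return pd.DataFrame({"node_id": np.arange(len(distances_km)), "lon": lons, "lat": lats})


class TestMatchNodes:
    def test_caps_at_radius_then_k(self):
        nodes = nodes_at_distances((0, 0), [10, 50, 150])
        assert match_nodes((0, 0), nodes, k=3) == [0, 1]
        assert match_nodes((0, 0), nodes, k=1) == [0]

    def test_empty_when_none_in_range(self):
        nodes = nodes_at_distances((0, 0), [120, 200])
        assert match_nodes((0, 0), nodes, k=3) == []

    def test_exact_tie_broken_by_ascending_node_id(self):
        # two nodes at identical distance east and west
        east = destination_point(0, 0, 90.0, 40.0)
        west = destination_point(0, 0, 270.0, 40.0)
        nodes = pd.DataFrame({"node_id": [7, 2],
                              "lon": [east[0], west[0]], "lat": [east[1], west[1]]})
        assert match_nodes((0, 0), nodes, k=1) == [2]


class TestSeriesStats:
    def test_order_statistics_of_1_to_100(self):
        v = np.arange(1, 101, dtype=float)
        assert series_stats(v, "median") == pytest.approx(50.5)
        # linear interpolation between order statistics
        assert series_stats(v, "p95") == pytest.approx(95.05)

    def test_constant_series_std_zero_and_empty_nan(self):
        assert series_stats(np.full(10, 3.3), "std") == 0.0
        assert np.isnan(series_stats([], "median"))
        assert np.isnan(series_stats([np.nan, np.nan], "p95"))

    def test_normal_sample_p95_matches_quantile(self):
        x = np.random.default_rng(0).normal(0, 1, 100_000)
        assert series_stats(x, "p95") == pytest.approx(1.6449, abs=0.02)


class TestNodeAveraging:
    def make_set(self, series_by_node, clc=(0.0, 0.0), dists=(10.0, 20.0), var="hs"):
        nodes = nodes_at_distances(clc, list(dists))
        arr = np.asarray(series_by_node, dtype=float)
        return NodeSeriesSet("era5_wave", nodes, np.arange(arr.shape[1], dtype=float),
                             {var: arr}, {var: "m"})

    def clcs(self):
        return pd.DataFrame({"cell_id": ["c0"], "lon": [0.0], "lat": [0.0]})

    def test_statistic_per_node_then_mean_over_nodes(self):
        nset = self.make_set([np.full(10, 1.0), np.full(10, 3.0)])
        out, prov = derive_node_indicators(self.clcs(), {"era5_wave": nset},
                                           MatchRule(k={"era5_wave": 2}))
        assert out.loc["c0", "H_s_med"] == pytest.approx(2.0)
        assert prov["c0"]["era5_wave"] == [0, 1]

    def test_nan_only_node_skipped_in_average(self):
        nset = self.make_set([np.full(10, np.nan), np.full(10, 3.0)])
        out, _ = derive_node_indicators(self.clcs(), {"era5_wave": nset},
                                        MatchRule(k={"era5_wave": 2}))
        assert out.loc["c0", "H_s_med"] == pytest.approx(3.0)

    def test_unmatched_class_gives_nan_for_exactly_its_indicators(self, small_study):
        """Remove one dataset class: only that class's node-averaged
        indicators turn NaN; everything else is untouched."""
        from coastnest.indicators import derive_indicators

        sets = {k: v for k, v in small_study.node_sets.items() if k != "gtsm"}
        table, _ = derive_indicators(small_study.grid, small_study.transects,
                                     sets, small_study.habitats)
        for col in CLASS_INDICATORS["gtsm"]:
            assert table[col].isna().all()
        ref = small_study.table
        for col in CLASS_INDICATORS["era5_wave"] + CLASS_INDICATORS["era5_atmos"]:
            assert np.allclose(table[col], ref[col], equal_nan=True)

    def test_scaling_series_scales_statistics_linearly(self):
        rng = np.random.default_rng(1)
        base = rng.gamma(2.0, 1.0, (2, 200))
        c = 3.7
        out1, _ = derive_node_indicators(self.clcs(), {"era5_wave": self.make_set(base)},
                                         MatchRule(k={"era5_wave": 2}))
        out2, _ = derive_node_indicators(self.clcs(), {"era5_wave": self.make_set(c * base)},
                                         MatchRule(k={"era5_wave": 2}))
        for col in ("H_s_med", "H_s_p95"):
            assert out2.loc["c0", col] == pytest.approx(c * out1.loc["c0", col])


def test_tidal_range_of_pure_sinusoid():
    t = np.arange(240, dtype=float)  # hourly, 10 days
    tide = np.sin(2 * np.pi * t / 12.0)[None, :]
    h = tidal_range_per_node(tide, dt_hours=1.0, window_hours=12.0)
    assert h[0] == pytest.approx(2.0)


class TestCurrentProximity:
    def make_current_set(self, clc, dists, medians):
        nodes = nodes_at_distances(clc, dists)
        arr = np.tile(np.asarray(medians, dtype=float)[:, None], (1, 10))
        return NodeSeriesSet("oras5", nodes, np.arange(10, dtype=float),
                             {"current": arr}, {"current": "m/s"})

    def clcs(self):
        return pd.DataFrame({"cell_id": ["c0"], "lon": [0.0], "lat": [0.0]})

    def test_nearest_qualifying_node(self):
        nset = self.make_current_set((0, 0), [40.0, 90.0], [0.5, 0.9])
        d = current_proximity(self.clcs(), nset)
        assert d.loc["c0"] == pytest.approx(40.0, rel=1e-6)

    def test_colocated_qualifying_node_gives_zero(self):
        nset = self.make_current_set((0, 0), [0.0, 50.0], [0.4, 0.4])
        assert current_proximity(self.clcs(), nset).loc["c0"] == 0.0

    def test_threshold_is_inclusive_at_point_three(self):
        nset = self.make_current_set((0, 0), [60.0], [0.3])
        assert current_proximity(self.clcs(), nset).loc["c0"] == pytest.approx(60.0, rel=1e-6)
        nset2 = self.make_current_set((0, 0), [60.0], [0.29999])
        assert np.isnan(current_proximity(self.clcs(), nset2).loc["c0"])


class TestHabitatDistance:
    def square_east(self, dist_km, side_km=50.0):
        # square patch whose near edge is dist_km due east of the origin
        west = dist_km / 111.1949266
        east = (dist_km + side_km) / 111.1949266
        half = side_km / 2.0 / 111.1949266
        return Polygon([(west, -half), (east, -half), (east, half), (west, half)])

    def test_inside_polygon_is_zero(self):
        poly = Polygon([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        assert habitat_distance((0, 0), [poly]) == 0.0

    def test_square_100km_east_matches_dense_oracle(self):
        poly = self.square_east(100.0)
        got = habitat_distance((0, 0), [poly])
        # oracle: sample the near edge at 10-m resolution
        west = 100.0 / 111.1949266
        half = 25.0 / 111.1949266
        lats = np.linspace(-half, half, 5001)
        oracle = np.min(haversine_km(0.0, 0.0, np.full_like(lats, west), lats))
        assert abs(got - oracle) < 1.0

    def test_nearest_of_two_patches(self):
        d = habitat_distance((0, 0), [self.square_east(70.0), self.square_east(20.0)])
        assert d == pytest.approx(20.0, abs=0.5)

    def test_empty_polygon_set_is_nan(self):
        assert np.isnan(habitat_distance((0, 0), []))


class TestGeophysical:
    def frame(self, angles, p_built=None):
        n = len(angles)
        return pd.DataFrame({
            "shoreline_angle": angles, "beta_ns": np.full(n, 0.02),
            "beta_bs": np.full(n, 0.06), "z_max": np.linspace(1, 5, n),
            "p_built": p_built if p_built is not None else np.zeros(n)})

    def test_equal_angles_zero_dispersion(self):
        out = derive_geophysical(self.frame([45.0] * 6))
        assert out["phi_std"] == pytest.approx(0.0, abs=1e-9)

    def test_wraparound_angles_use_circular_statistics(self):
        out = derive_geophysical(self.frame([359.0, 1.0]))
        assert out["phi_std"] == pytest.approx(1.0, abs=0.01)
        # the linear convention (kept for dataset matching) gets this wrong
        linear = derive_geophysical(self.frame([359.0, 1.0]), circular_angles=False)
        assert linear["phi_std"] > 100.0

    def test_built_fraction_is_mean(self):
        out = derive_geophysical(self.frame([0.0, 0.0], p_built=[0.0, 100.0]))
        assert out["p_built"] == pytest.approx(50.0)


class TestMADm:
    def test_constant_vector_is_zero(self):
        assert compute_madm([4.0, 4.0, 4.0]) == 0.0

    def test_hand_computed_example(self):
        # median 2, absolute deviations {1, 0, 1} -> MAD 1 -> MADm 0.5
        assert compute_madm([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_zero_median_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(compute_madm([-1.0, 0.0, 1.0]))

    @settings(max_examples=50, deadline=None)
    @given(scale=st.floats(0.1, 100.0),
           seed=st.integers(0, 1000))
    def test_invariant_to_positive_rescaling(self, scale, seed):
        x = np.random.default_rng(seed).gamma(2.0, 1.0, 20) + 0.1
        assert compute_madm(scale * x) == pytest.approx(compute_madm(x), rel=1e-9)


def test_p95_never_below_median_on_study_table(small_study):
    table = small_study.table
    for med_col, p95_col in (("H_s_med", "H_s_p95"), ("T_p_med", "T_p_p95"),
                             ("h_S_med", "h_S_p95"), ("U10_med", "U10_p95")):
        both = table[[med_col, p95_col]].dropna()
        assert (both[p95_col] >= both[med_col] - 1e-12).all()


def test_full_table_has_all_22_indicators(small_study):
    for col in INDICATOR_COLUMNS:
        assert col in small_study.table.columns
    assert len(small_study.table) == len(small_study.grid.cells)
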