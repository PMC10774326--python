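"""Suitability classification, correlations, regional summaries, KS tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from shapely.geometry import Polygon

from coastnest.clustering import ClusterAssignment
from coastnest.suitability import (
    assign_regions,
    bh_adjust,
    classify_suitability,
    cluster_stats,
    correlate_clusters,
    cross_species_means,
    expansion_ratio,
    ks_compare,
    rho_category,
    round_half_even,
    spearman_rho,
    summarize_regions,
)


def make_assignment(cluster_of: dict, k: int) -> ClusterAssignment:
    return ClusterAssignment(bmu=pd.Series(cluster_of), k=k)


def make_table(n, nesting_flags, indicator=None):
    idx = [f"c{i}" for i in range(n)]
    return pd.DataFrame({
        "x": indicator if indicator is not None else np.arange(n, dtype=float),
        "nesting_CM": nesting_flags,
    }, index=idx)


class TestClusterStats:
    def test_counts_and_percentage(self):
        table = make_table(10, [1, 1, 1] + [0] * 7)
        assignment = make_assignment({f"c{i}": 0 for i in range(10)}, k=2)
        stats = cluster_stats(assignment, table, "CM", ["x"])
        assert stats.loc[0, "n"] == 10
        assert stats.loc[0, "pct_nesting"] == pytest.approx(30.0)
        # empty cluster flagged with n = 0 and NaN statistics
        assert stats.loc[1, "n"] == 0
        assert np.isnan(stats.loc[1, "pct_nesting"])

    def test_single_member_median_is_its_value(self):
        table = make_table(3, [0, 0, 1], indicator=[2.0, 4.0, 9.0])
        assignment = make_assignment({"c0": 0, "c1": 0, "c2": 1}, k=2)
        stats = cluster_stats(assignment, table, "CM", ["x"])
        assert stats.loc[1, "x"] == 9.0

    def test_id_mismatch_rejected(self):
        table = make_table(2, [0, 1])
        assignment = make_assignment({"zz": 0}, k=1)
        with pytest.raises(ValueError, match="missing"):
            cluster_stats(assignment, table, "CM", ["x"])


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_hand_ranked_example_with_ties(self):
        # y ranks with average ranks: (1, 2, 3.5, 5, 3.5) -> rho = 8/sqrt(95)
        rho = spearman_rho([1, 2, 3, 4, 5], [5, 6, 7, 8, 7])
        assert rho == pytest.approx(0.8208, abs=1e-3)

    def test_constant_input_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_agrees_with_rank_pearson_oracle(self):
        """Independent oracle: Pearson correlation of average ranks."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = rng.integers(0, 8, n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rx = sps.rankdata(x)
            ry = sps.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-9)

    def test_category_cuts_are_inclusive(self):
        assert rho_category(0.3) == "significant"
        assert rho_category(-0.3) == "significant"
        assert rho_category(0.299) == "weak"
        assert rho_category(0.1) == "weak"
        assert rho_category(0.0999) == "insignificant"
        assert rho_category(float("nan")) == "insignificant"


class TestCorrelateClusters:
    def test_monotone_medians(self):
        stats = pd.DataFrame({
            "n": [5, 5, 5, 5], "n_nesting": [0, 1, 2, 4],
            "pct_nesting": [0.0, 20.0, 40.0, 80.0],
            "x": [1.0, 2.0, 3.0, 4.0], "y": [4.0, 3.0, 2.0, 1.0]})
        result = correlate_clusters(stats, ["x", "y"], "CM")
        assert result.rho["x"] == pytest.approx(1.0)
        assert result.rho["y"] == pytest.approx(-1.0)
        assert result.category["x"] == "significant"
        assert result.p_n == pytest.approx(75.0)

    def test_empty_clusters_excluded(self):
        stats = pd.DataFrame({
            "n": [5, 0, 5, 5], "n_nesting": [0, 0, 2, 4],
            "pct_nesting": [0.0, np.nan, 40.0, 80.0],
            "x": [1.0, np.nan, 3.0, 4.0]})
        result = correlate_clusters(stats, ["x"], "CM")
        assert result.n_clusters_used == 3
        assert result.rho["x"] == pytest.approx(1.0)

    def test_too_few_clusters_rejected(self):
        stats = pd.DataFrame({"n": [5, 0], "n_nesting": [1, 0],
                              "pct_nesting": [20.0, np.nan], "x": [1.0, np.nan]})
        with pytest.raises(ValueError):
            correlate_clusters(stats, ["x"], "CM")


class TestClassify:
    def test_threshold_inclusive_at_ten_percent(self):
        # one cluster of 10 with exactly 1 nesting member -> 10% -> S
        table = make_table(10, [1] + [0] * 9)
        assignment = make_assignment({f"c{i}": 0 for i in range(10)}, k=1)
        out = classify_suitability(assignment, table, "CM", threshold_pct=10.0)
        assert out.loc["c0", "category"] == "O"
        assert (out.loc[[f"c{i}" for i in range(1, 10)], "category"] == "S").all()

    def test_all_nesting_clusters_have_no_suitable_members(self):
        table = make_table(4, [1, 1, 1, 1])
        assignment = make_assignment({f"c{i}": 0 for i in range(4)}, k=1)
        out = classify_suitability(assignment, table, "CM")
        assert (out["category"] == "O").all()

    def test_vacuous_threshold_gives_no_suitable(self):
        table = make_table(10, [1] + [0] * 9)
        assignment = make_assignment({f"c{i}": 0 for i in range(10)}, k=1)
        out = classify_suitability(assignment, table, "CM", threshold_pct=101.0)
        assert (out["category"] == "U").sum() == 9

    def test_unclustered_cells_are_unsuitable_and_flagged(self):
        table = make_table(5, [1, 0, 0, 0, 0])
        assignment = make_assignment({f"c{i}": 0 for i in range(4)}, k=1)  # c4 missing
        out = classify_suitability(assignment, table, "CM")
        assert out.loc["c4", "category"] == "U"
        assert bool(out.loc["c4", "unclustered"])
        assert not out.loc["c0", "unclustered"]

    def test_partition_every_cell_exactly_one_category(self):
        table = make_table(10, [1, 1] + [0] * 8)
        assignment = make_assignment({f"c{i}": i % 2 for i in range(10)}, k=2)
        out = classify_suitability(assignment, table, "CM")
        assert set(out["category"]) <= {"O", "S", "U"}
        assert len(out) == len(table)


class TestRegionSummaries:
    def test_printed_category_counts_reproduce_percentages(self):
        # 85 observed, 261 suitable, 99 unsuitable -> P_O 19.1%, P_S 77.8%
        cats = pd.DataFrame({"CC": ["O"] * 85 + ["S"] * 261 + ["U"] * 99})
        cats.index = [f"c{i}" for i in range(len(cats))]
        region_of = pd.Series("Mediterranean", index=cats.index)
        summary = summarize_regions(cats, region_of, include_global=False)
        assert round_half_even(summary.loc["Mediterranean", "P_O_CC"]) == 19.1
        assert round_half_even(summary.loc["Mediterranean", "P_S_CC"]) == 77.8

    def test_all_observed_region_is_saturated(self):
        cats = pd.DataFrame({"CM": ["O"] * 7}, index=[f"c{i}" for i in range(7)])
        summary = summarize_regions(cats)
        assert summary.loc["Global", "P_O_CM"] == 100.0
        assert summary.loc["Global", "P_S_CM"] == 100.0

    def test_ps_never_below_po_and_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        table = make_table(60, rng.integers(0, 2, 60))
        assignment = make_assignment({f"c{i}": i % 6 for i in range(60)}, k=6)
        ps = []
        for thr in (10.0, 50.0):
            out = classify_suitability(assignment, table, "CM", threshold_pct=thr)
            cats = pd.DataFrame({"CM": out["category"]})
            s = summarize_regions(cats)
            assert s.loc["Global", "P_S_CM"] >= s.loc["Global", "P_O_CM"]
            ps.append(s.loc["Global", "P_S_CM"])
        assert ps[1] <= ps[0]  # raising the threshold cannot add suitable cells

    def test_species_absent_from_region_skipped_in_mean(self):
        cats = pd.DataFrame({
            "CC": ["O", "S", "U", "U"],
            "LO": ["U", "U", "U", "U"],   # no observed nesting: excluded
        }, index=list("abcd"))
        summary = summarize_regions(cats)
        assert np.isnan(summary.loc["Global", "P_O_LO"])
        assert summary.loc["Global", "P_O_mean"] == pytest.approx(25.0)
        assert summary.loc["Global", "P_S_mean"] == pytest.approx(50.0)

    def test_cross_species_means_and_ratio_helpers(self):
        df = pd.DataFrame({"P_O_CC": [10.0], "P_O_CM": [np.nan],
                           "P_S_CC": [30.0], "P_S_CM": [np.nan]}, index=["Global"])
        out = cross_species_means(df)
        assert out.loc["Global", "P_O_mean"] == 10.0
        assert expansion_ratio(out) == pytest.approx(3.0)


class TestAssignRegions:
    def test_point_in_polygon_and_outside_nan(self):
        regions = {"A": Polygon([(0, 0), (2, 0), (2, 2), (0, 2)]),
                   "B": Polygon([(5, 0), (7, 0), (7, 2), (5, 2)])}
        clcs = pd.DataFrame({"cell_id": ["x", "y", "z"],
                             "lon": [1.0, 6.0, 10.0], "lat": [1.0, 1.0, 1.0]})
        out = assign_regions(clcs, regions)
        assert out.loc["x"] == "A"
        assert out.loc["y"] == "B"
        assert pd.isna(out.loc["z"])

    def test_overlapping_regions_rejected(self):
        regions = {"A": Polygon([(0, 0), (2, 0), (2, 2), (0, 2)]),
                   "B": Polygon([(1, 1), (3, 1), (3, 3), (1, 3)])}
        clcs = pd.DataFrame({"cell_id": ["x"], "lon": [1.0], "lat": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            assign_regions(clcs, regions)


class TestKS:
    def test_identical_samples(self):
        idx = [f"c{i}" for i in range(40)]
        cats = pd.Series(["O"] * 10 + ["S"] * 10 + ["U"] * 20, index=idx)
        table = pd.DataFrame({"x": np.tile(np.arange(10.0), 4)}, index=idx)
        out = ks_compare(cats, table, ["x"])
        row = out[(out["pair"] == "O|S")].iloc[0]
        assert row["D"] == 0.0
        assert row["p"] == 1.0
        assert row["p_adj"] == 1.0

    def test_well_separated_distributions_significant(self):
        rng = np.random.default_rng(0)
        idx = [f"c{i}" for i in range(600)]
        cats = pd.Series(["O"] * 200 + ["S"] * 200 + ["U"] * 200, index=idx)
        x = np.concatenate([rng.normal(0, 1, 400), rng.normal(3, 1, 200)])
        out = ks_compare(cats, pd.DataFrame({"x": x}, index=idx), ["x"])
        assert out.loc[out["pair"] == "O|U", "p_adj"].iloc[0] < 1e-3
        assert out.loc[out["pair"] == "S|U", "p_adj"].iloc[0] < 1e-3

    def test_bh_step_up_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_bh_matches_hand_rolled_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(0, 1, 3)
            # independent step-up oracle
            order = np.argsort(p)
            m = len(p)
            adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            oracle = np.empty(m)
            oracle[order] = np.minimum(adj_sorted, 1.0)
            assert np.allclose(bh_adjust(p), oracle, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(0, 1, 3)
            assert (bh_adjust(p) >= p - 1e-15).all()

    def test_small_category_skipped_with_warning(self):
        idx = [f"c{i}" for i in range(22)]
        cats = pd.Series(["O"] * 1 + ["S"] * 10 + ["U"] * 11, index=idx)
        table = pd.DataFrame({"x": np.arange(22.0)}, index=idx)
        with pytest.warns(RuntimeWarning, match="skipped"):
            out = ks_compare(cats, table, ["x"])
        assert np.isnan(out.loc[out["pair"] == "O|S", "D"]).all()
        assert np.isfinite(out.loc[out["pair"] == "S|U", "D"]).all()
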