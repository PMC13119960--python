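import numpy as np
import pandas as pd
import pytest

import woundclust as wc


def toy_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes,
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestStandardize:
    def test_two_sample_zscores(self):
        b = wc.standardize(toy_matrix([[0, 2]]))
        assert b.loc["g0"].tolist() == [-1.0, 1.0]  # population sd = 1

    def test_constant_gene_named_in_error(self):
        with pytest.raises(ValueError, match="g0"):
            wc.standardize(toy_matrix([[5, 5, 5]]))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = toy_matrix(rng.uniform(0, 20, (10, 30)))
        once = wc.standardize(m)
        twice = wc.standardize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)

    def test_mean_zero_sd_one_invariants(self, run42):
        b = run42.standardized
        assert np.abs(b.mean(axis=1)).max() < 1e-9
        assert np.abs(b.std(axis=1, ddof=0) - 1).max() < 1e-9

    def test_uses_supplied_stats(self, run42):
        direct = wc.standardize(run42.filtered)
        via_stats = wc.standardize(run42.filtered, run42.stats)
        assert np.allclose(direct.to_numpy(), via_stats.to_numpy(), atol=1e-12)


class TestClusterMeanSeries:
    def test_singleton_equals_gene_row(self, run42):
        gene = run42.filtered.index[0]
        s = wc.cluster_mean_series(run42.standardized, [gene])
        assert np.allclose(s.to_numpy(), run42.standardized.loc[gene].to_numpy())

    def test_opposite_rows_cancel(self):
        b = wc.standardize(toy_matrix([[0, 1, 2, 4], [4, 3, 2, 0]]))
        s = wc.cluster_mean_series(b, ["g0", "g1"])
        assert np.allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_empty_cluster_rejected(self, run42):
        with pytest.raises(ValueError, match="empty"):
            wc.cluster_mean_series(run42.standardized, [])

    def test_series_bounded_by_member_range(self, run42):
        cl = run42.retained[0]
        s = wc.cluster_mean_series(run42.standardized, cl)
        member_b = run42.standardized.loc[list(cl.members)]
        assert (s <= member_b.max(axis=0) + 1e-12).all()
        assert (s >= member_b.min(axis=0) - 1e-12).all()

    def test_equals_independent_average_of_member_rows(self, run42):
        cl = run42.labelled("ecm")
        s = wc.cluster_mean_series(run42.standardized, cl)
        manual = sum(
            run42.standardized.loc[g].to_numpy() for g in cl.members
        ) / cl.size
        assert np.allclose(s.to_numpy(), manual, atol=1e-12)

    def test_immune_edge_series_peaks_during_inflammation(self, run42):
        s = wc.cluster_mean_series(run42.standardized, run42.labelled("immune"))
        summary = wc.summarize_by_day(s, run42.meta_retained)
        edge = summary[(summary["location"] == "edge") & ~summary["from_baseline"]]
        peak_day = edge.loc[edge["mean"].idxmax(), "day"]
        assert 1 <= peak_day <= 7


class TestSummarizeByDay:
    def make_meta(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "pig", "wound", "day", "location"])

    def test_identical_replicates(self):
        meta = self.make_meta([("a", "P", "W1", 2, "edge"), ("b", "P", "W2", 2, "edge")])
        s = pd.Series([3.0, 3.0], index=["a", "b"])
        out = wc.summarize_by_day(s, meta)
        assert out.loc[0, "mean"] == 3.0
        assert out.loc[0, "sd"] == 0.0

    def test_population_sd(self):
        meta = self.make_meta([("a", "P", "W1", 2, "edge"), ("b", "P", "W2", 2, "edge")])
        out = wc.summarize_by_day(pd.Series([1.0, 3.0], index=["a", "b"]), meta)
        assert out.loc[0, "mean"] == 2.0
        assert out.loc[0, "sd"] == 1.0

    def test_baseline_attached_to_both_locations(self):
        meta = self.make_meta(
            [("bl", "P", "B", 0, "baseline"), ("e", "P", "W", 1, "edge")]
        )
        out = wc.summarize_by_day(pd.Series([2.0, 5.0], index=["bl", "e"]), meta)
        day0 = out[out["day"] == 0]
        assert set(day0["location"]) == {"edge", "center"}
        assert day0["from_baseline"].all()
        assert (day0["mean"] == 2.0).all()

    def test_replicate_order_invariance(self, run42):
        s = wc.cluster_mean_series(run42.standardized, run42.labelled("ecm"))
        shuffled = s.sample(frac=1, random_state=1)
        a = wc.summarize_by_day(s, run42.meta_retained)
        b = wc.summarize_by_day(shuffled, run42.meta_retained)
        pd.testing.assert_frame_equal(a, b)

    def test_muscle_center_more_variable_than_edge_days_1_5(self, run42):
        s = wc.cluster_mean_series(run42.standardized, run42.labelled("muscle"))
        out = wc.summarize_by_day(s, run42.meta_retained)
        window = out[out["day"].between(1, 5) & ~out["from_baseline"]]
        for day, grp in window.groupby("day"):
            sd = grp.set_index("location")["sd"]
            assert sd["center"] > sd["edge"]

    def test_immune_center_minus_edge_nonnegative_days_7_16(self, run42):
        s = wc.cluster_mean_series(run42.standardized, run42.labelled("immune"))
        out = wc.summarize_by_day(s, run42.meta_retained)
        window = out[out["day"].between(7, 16) & ~out["from_baseline"]]
        diff = window.pivot(index="day", columns="location", values="mean")
        assert ((diff["center"] - diff["edge"]) >= 0).all()


class TestPairScatter:
    def test_identical_vectors_on_diagonal(self):
        m = toy_matrix([[1, 1], [7, 7], [4, 4]])
        m.columns = ["e", "c"]
        pair = {"wound": "W", "day": 1, "edge_sample": "e", "center_sample": "c"}
        sc = wc.pair_scatter(m, pair)
        assert len(sc) == 3
        assert np.allclose(sc["edge"], sc["center"])

    def test_epithelial_genes_below_diagonal_on_day3(self, run42):
        pairs = run42.pairs
        clean = pairs[(pairs["day"] == 3) & ~pairs["excluded"]].iloc[0]
        epi = set(run42.truth.members("epithelial"))
        sc = wc.pair_scatter(run42.matrix_retained, clean, {"epithelial": epi})
        hi = sc[sc["highlight"] == "epithelial"]
        assert len(hi) == 30
        assert (hi["edge"] > hi["center"]).all()

    def test_empty_highlight_sets(self, run42):
        clean = run42.pairs[~run42.pairs["excluded"]].iloc[0]
        sc = wc.pair_scatter(run42.matrix_retained, clean, {})
        assert (sc["highlight"] == "").all()

    def test_excluded_pair_rejected(self, run42):
        bad = run42.pairs[run42.pairs["excluded"]].iloc[0]
        with pytest.raises(ValueError, match="excluded"):
            wc.pair_scatter(run42.matrix, bad)


class TestTrajectory:
    def test_same_series_lies_on_diagonal(self, run42):
        s = wc.cluster_mean_series(run42.standardized, run42.labelled("immune"))
        tr = wc.trajectory(s, s, run42.meta_retained)
        assert np.allclose(tr["a"], tr["b"])

    def test_single_day_one_point_path(self):
        meta = pd.DataFrame(
            {"sample_id": ["x", "y"], "pig": "P", "wound": ["W1", "W2"],
             "day": 4, "location": "edge"}
        )
        s = pd.Series([1.0, 2.0], index=["x", "y"])
        tr = wc.trajectory(s, s, meta)
        assert len(tr) == 1
        assert tr.loc[0, "is_start"] and tr.loc[0, "is_end"]

    def test_mismatched_sample_sets_rejected(self, run42):
        s = wc.cluster_mean_series(run42.standardized, run42.labelled("immune"))
        with pytest.raises(ValueError, match="different sample sets"):
            wc.trajectory(s, s.iloc[:-1], run42.meta_retained)

    def test_center_path_round_trip(self, run42):
        epi = wc.cluster_mean_series(run42.standardized, run42.labelled("epithelial"))
        imm = wc.cluster_mean_series(run42.standardized, run42.labelled("immune"))
        tr = wc.trajectory(epi, imm, run42.meta_retained)
        center = tr[tr["location"] == "center"].set_index("day")
        start = center.loc[0, ["a", "b"]].to_numpy(dtype=float)
        end = center.loc[21, ["a", "b"]].to_numpy(dtype=float)
        peak_day = center["b"].idxmax()
        peak = center.loc[peak_day, ["a", "b"]].to_numpy(dtype=float)
        # immune activation rises above baseline, then the path returns
        assert center.loc[peak_day, "b"] > center.loc[0, "b"]
        assert np.linalg.norm(end - start) < np.linalg.norm(peak - start)


class TestContaminationFlags:
    def test_all_zero_series_no_flags(self, run42):
        zero = pd.Series(0.0, index=run42.matrix_retained.columns)
        rep = wc.flag_contaminated_samples(zero, run42.meta_retained)
        assert rep.flagged == []

    def test_muscle_cluster_flags_exactly_planted_centers(self, run42):
        s = wc.cluster_mean_series(run42.standardized, run42.labelled("muscle"))
        rep = wc.flag_contaminated_samples(s, run42.meta_retained, tau=1.0)
        planted = set(run42.truth.contaminated_samples("muscle"))
        assert set(rep.flagged) == planted

    def test_six_pairs_and_twenty_percent(self, run42):
        s = wc.cluster_mean_series(run42.standardized, run42.labelled("muscle"))
        rep = wc.flag_contaminated_samples(s, run42.meta_retained, tau=1.0)
        counts = wc.count_flagged_pairs(rep, run42.pairs, days=(1, 5), location="center")
        assert counts["flagged_pairs"] == 6
        assert counts["total_pairs"] == 30
        assert counts["percent"] == pytest.approx(20.0)

    def test_nonfinite_tau_rejected(self, run42):
        s = pd.Series(0.0, index=run42.matrix_retained.columns)
        with pytest.raises(ValueError, match="tau"):
            wc.flag_contaminated_samples(s, run42.meta_retained, tau=float("nan"))
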