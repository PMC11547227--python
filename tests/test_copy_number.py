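"""Purity rescaling, segment repair, LGA counting, profile comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ascites_cfdna.copy_number import (
    annotate_copy_number,
    assign_bins_to_segments,
    call_gene_amplifications,
    cluster_profiles,
    cn_from_log2,
    count_lga,
    naive_segment,
    profile_divergence,
    region_density_test,
    repair_unreliable_segments,
    round_half_up,
)

MB = 1_000_000


def seg_table(rows):
    """rows: (chrom, start, end, cn_int[, depth])"""
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "cn_int", "depth"][: len(rows[0])])
    df["cn_est"] = df["cn_int"].astype(float)
    return df


class TestRescaling:
    @pytest.mark.parametrize("log2r,t,expected", [
        (0.0, 1.0, 2.0),
        (-1.0, 1.0, 1.0),
        (np.log2(0.75), 0.5, 1.0),
    ])
    def test_known_points(self, log2r, t, expected):
        assert cn_from_log2(log2r, t) == pytest.approx(expected)

    def test_inverts_simulator_forward_model(self):
        """cn -> log2((t*cn + 2(1-t))/2) -> cn round-trips exactly."""
        for t in (0.1, 0.3, 0.5, 0.88, 1.0):
            cn = np.array([0, 1, 2, 3, 5, 12], dtype=float)
            log2r = np.log2(np.maximum(t * cn + 2 * (1 - t), 1e-9) / 2)
            assert np.allclose(cn_from_log2(log2r, t), cn, atol=1e-6)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError):
            cn_from_log2(0.0, 0.0)

    def test_half_up_rounding(self):
        assert list(round_half_up(np.array([2.5, 3.5, 2.49]))) == [3, 4, 2]


class TestRepair:
    def test_high_depth_tail_repaired_from_single_flank(self):
        segs = seg_table([("chr1", i * 20 * MB, (i + 1) * 20 * MB, cn, d)
                          for i, (cn, d) in enumerate(zip([2, 2, 2, 2, 30],
                                                          [100, 100, 100, 100, 1000]))])
        out = repair_unreliable_segments(segs)
        assert out["unreliable"].tolist() == [False] * 4 + [True]
        assert out["cn_est"].iloc[-1] == 2.0
        assert out["cn_int"].iloc[-1] == 2

    def test_equal_depths_unchanged(self):
        segs = seg_table([("chr1", 0, 10, 2, 100), ("chr1", 10, 20, 3, 100),
                          ("chr1", 20, 30, 2, 100)])
        out = repair_unreliable_segments(segs)
        assert not out["unreliable"].any()
        assert out["cn_est"].tolist() == [2.0, 3.0, 2.0]

    def test_interior_outlier_gets_neighbour_mean(self):
        segs = seg_table([("chr1", 0, 10, 1, 100), ("chr1", 10, 20, 9, 5000),
                          ("chr1", 20, 30, 3, 101), ("chr1", 30, 40, 3, 99),
                          ("chr1", 40, 50, 3, 100)])
        out = repair_unreliable_segments(segs)
        assert out["unreliable"].iloc[1]
        assert out["cn_est"].iloc[1] == pytest.approx(2.0)

    def test_untouched_below_cutoff(self):
        rng = np.random.default_rng(0)
        depths = rng.normal(100, 5, 10)
        segs = seg_table([("chr1", i * 10, (i + 1) * 10, 2, d)
                          for i, d in enumerate(depths)])
        out = repair_unreliable_segments(segs)
        assert out["cn_est"].tolist() == segs["cn_est"].tolist()


def brute_force_lga(segs: pd.DataFrame, min_len=10 * MB) -> int:
    """Literal enumeration of qualifying-boundary pairs."""
    total = 0
    for chrom in segs["chromosome"].unique():
        sub = segs[segs["chromosome"] == chrom].sort_values("start")
        qual = [(r["cn_int"]) for _, r in sub.iterrows()
                if r["end"] - r["start"] > min_len]
        total += sum(1 for a, b in zip(qual, qual[1:]) if a != b)
    return total


class TestLga:
    def test_worked_example(self):
        lens_cns = [(12, 2), (15, 1), (11, 1), (14, 3)]
        pos, rows = 0, []
        for ln, cn in lens_cns:
            rows.append(("chr1", pos, pos + ln * MB, cn))
            pos += ln * MB
        assert count_lga(seg_table(rows)).lga_count == 2

    def test_all_short_counts_zero(self):
        rows = [("chr1", i * MB, (i + 1) * MB, cn) for i, cn in enumerate([2, 3, 1])]
        assert count_lga(seg_table(rows)).lga_count == 0

    def test_short_intervener_skipped(self):
        rows = [("chr1", 0, 12 * MB, 2), ("chr1", 12 * MB, 16 * MB, 5),
                ("chr1", 16 * MB, 31 * MB, 1)]
        res = count_lga(seg_table(rows))
        assert res.lga_count == 1
        assert res.breakpoints == [("chr1", 16 * MB)]

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            rows, pos = [], 0
            chrom = "chr1"
            for _ in range(rng.integers(1, 12)):
                ln = int(rng.integers(1, 25)) * MB
                rows.append((chrom, pos, pos + ln, int(rng.integers(0, 5))))
                pos += ln
                if rng.random() < 0.2:
                    chrom, pos = f"chr{rng.integers(2, 5)}", 0
            segs = seg_table(rows).drop_duplicates(["chromosome", "start"])
            assert count_lga(segs).lga_count == brute_force_lga(segs)


class TestGeneAmplification:
    def genes(self):
        return pd.DataFrame({"chromosome": ["chr1"], "start": [10 * MB],
                             "end": [11 * MB], "name": ["MYC"]})

    def test_fully_contained_high_cn(self):
        segs = seg_table([("chr1", 0, 50 * MB, 29)])
        out = call_gene_amplifications(segs, self.genes())
        assert out.loc[0, "fold"] == pytest.approx(14.5)
        assert out.loc[0, "amplified"]

    def test_neutral_not_amplified(self):
        segs = seg_table([("chr1", 0, 50 * MB, 2)])
        assert not call_gene_amplifications(segs, self.genes()).loc[0, "amplified"]

    def test_split_gene_weighted_mean_strict_threshold(self):
        segs = seg_table([("chr1", 0, int(10.5 * MB), 2), ("chr1", int(10.5 * MB), 50 * MB, 6)])
        out = call_gene_amplifications(segs, self.genes())
        assert out.loc[0, "cn_est"] == pytest.approx(4.0)
        assert out.loc[0, "fold"] == pytest.approx(2.0)
        assert not out.loc[0, "amplified"]  # strict >

    def test_uncovered_gene_is_nan(self):
        segs = seg_table([("chr2", 0, 50 * MB, 2)])
        out = call_gene_amplifications(segs, self.genes())
        assert np.isnan(out.loc[0, "cn_est"]) and not out.loc[0, "amplified"]


class TestDivergence:
    def bins(self, n=10):
        return pd.DataFrame({"chromosome": "chr1",
                             "start": np.arange(n) * MB,
                             "end": (np.arange(n) + 1) * MB})

    def test_identical_zero(self):
        segs = seg_table([("chr1", 0, 10 * MB, 2)])
        assert profile_divergence(self.bins(), self.bins(), segs, segs) == 0.0

    def test_three_of_ten(self):
        a = seg_table([("chr1", 0, 10 * MB, 2)])
        b = seg_table([("chr1", 0, 3 * MB, 4), ("chr1", 3 * MB, 10 * MB, 2)])
        assert profile_divergence(self.bins(), self.bins(), a, b) == pytest.approx(30.0)

    def test_grid_mismatch_errors(self):
        segs = seg_table([("chr1", 0, 10 * MB, 2)])
        with pytest.raises(ValueError, match="grid"):
            profile_divergence(self.bins(10), self.bins(9), segs, segs)


class TestProfileClustering:
    def test_duplicate_sample_merges_first(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 50)
        m = pd.DataFrame([base, base, rng.normal(0, 1, 50)],
                         index=["dup1", "dup2", "other"])
        link, labels = cluster_profiles(m)
        assert set(link[0, :2]) == {0, 1}  # first merge joins the duplicates
        assert labels["dup1"] == labels["dup2"] != labels["other"]

    def test_anticorrelated_distance_two(self):
        x = np.linspace(-1, 1, 30)
        m = pd.DataFrame([x, -x], index=["a", "b"])
        link, _ = cluster_profiles(m)
        assert link[0, 2] == pytest.approx(2.0)

    def test_constant_profile_handled(self, caplog):
        m = pd.DataFrame([np.zeros(20), np.random.default_rng(0).normal(size=20)],
                         index=["flat", "x"])
        with caplog.at_level("WARNING"):
            link, _ = cluster_profiles(m)
        assert link[0, 2] == pytest.approx(1.0)

    def test_patient_matched_samples_cluster_together(self, default_cohort):
        c = default_cohort
        sids = list(c.manifest["sample_id"])
        m = pd.DataFrame({s: c.bins[s]["log2"].to_numpy() for s in sids}).T
        link, labels = cluster_profiles(m)
        part = dict(zip(c.manifest["sample_id"], c.manifest["participant_id"]))
        for p in c.manifest["participant_id"].unique():
            ids = [s for s in sids if part[s] == p]
            assert len({labels[s] for s in ids}) == 1


class TestRegionDensity:
    def test_three_pair_worked_example(self):
        t, df, p = region_density_test([10, 12, 11], [8, 9, 7])
        assert t == pytest.approx(3 / (1 / np.sqrt(3)), rel=1e-6)
        assert df == 2
        assert p == pytest.approx(0.0351, abs=5e-4)

    def test_symmetry_under_region_swap(self):
        t1, _, p1 = region_density_test([10, 12, 11], [8, 9, 7])
        t2, _, p2 = region_density_test([8, 9, 7], [10, 12, 11])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_identical_pairs_undefined(self):
        t, df, p = region_density_test([5, 6, 7], [4, 5, 6])
        assert np.isnan(t) and np.isnan(p)

    def test_matches_textbook_formula_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(3, 20)
            a, b = rng.normal(10, 2, n), rng.normal(9, 2, n)
            t, df, p = region_density_test(a, b)
            d = a - b
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p_ref = 2 * stats.t.sf(abs(t_ref), n - 1)
            assert t == pytest.approx(t_ref)
            assert p == pytest.approx(p_ref)


class TestNaiveSegmenter:
    def test_merges_until_jump(self):
        bins = pd.DataFrame({
            "chromosome": "chr1",
            "start": np.arange(6) * MB, "end": (np.arange(6) + 1) * MB,
            "log2": [0.0, 0.05, 0.02, 0.9, 0.95, 0.88],
        })
        segs = naive_segment(bins)
        assert len(segs) == 2
        assert segs["end"].tolist() == [3 * MB, 6 * MB]
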