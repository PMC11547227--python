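"""CCF computation, exclusion rules, clone clustering, prevalence shifts."""

import numpy as np
import pandas as pd
import pytest

from ascites_cfdna.clonal import (
    ClonalCluster,
    ccf,
    ccf_matrix,
    cluster_ccf,
    detect_prevalence_shifts,
    prepare_clonal_inputs,
    unrepresented_clone_warning,
)
from ascites_cfdna.purity import vaf_from_purity


class TestCcf:
    def test_neutral_clonal_variant(self):
        assert ccf(0.25, 0.5, 2) == pytest.approx(1.0)

    def test_zero_vaf(self):
        assert ccf(0.0, 0.7, 3) == 0.0

    def test_double_hit_point_consistency(self):
        """The TP53 anchor VAF at CN 1 maps back to CCF 1 exactly."""
        for t in (0.3, 0.5, 0.88):
            assert ccf(vaf_from_purity(t), t, 1) == pytest.approx(1.0, abs=1e-12)

    def test_multiplicity_rounding(self):
        # v=0.375, t=0.5, cn=2: scaled = 1.5 -> m rounds half-up to 2 -> 0.75
        assert ccf(0.375, 0.5, 2) == pytest.approx(0.75)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ccf(0.2, 0.0, 2)
        with pytest.raises(ValueError):
            ccf(0.2, 0.5, 0)


def segments_for(cn_by_chrom):
    rows = [{"chromosome": c, "start": 0, "end": 10_000_000, "cn_int": cn}
            for c, cn in cn_by_chrom.items()]
    return pd.DataFrame(rows)


def variant_rows(spec):
    """spec: list of (chrom, pos, sample_id, alt, depth)"""
    return pd.DataFrame([
        {"chrom": c, "pos": p, "ref": "A", "alt_allele": "T", "alt": "T",
         "sample_id": s, "alt_count": a, "depth": d, "vaf": a / d}
        for c, p, s, a, d in spec
    ])


class TestPrepareInputs:
    def test_cn0_in_any_sample_excludes_everywhere(self):
        v = variant_rows([("chrA", 100, "S1", 30, 100), ("chrA", 100, "S2", 30, 100),
                          ("chrB", 200, "S1", 20, 100), ("chrB", 200, "S2", 20, 100)])
        segs = {"S1": segments_for({"chrA": 2, "chrB": 2}),
                "S2": segments_for({"chrA": 0, "chrB": 2})}
        rows, excl = prepare_clonal_inputs(v, {"S1": 0.8, "S2": 0.8}, segs)
        assert set(rows["chrom"]) == {"chrB"}
        assert excl.loc[excl["reason"] == "cn0", "key"].tolist() == ["chrA:100:A:T"]

    def test_low_purity_high_vaf_dropped(self):
        v = variant_rows([("chrA", 100, "S1", 35, 100), ("chrA", 100, "S2", 40, 100),
                          ("chrB", 200, "S1", 10, 100), ("chrB", 200, "S2", 10, 100)])
        segs = {s: segments_for({"chrA": 2, "chrB": 2}) for s in ("S1", "S2")}
        rows, excl = prepare_clonal_inputs(v, {"S1": 0.25, "S2": 0.8}, segs)
        # vaf 0.35 in the 0.25-purity sample -> the variant goes entirely
        assert set(rows["chrom"]) == {"chrB"}
        assert excl["reason"].tolist() == ["low-purity-vaf"]

    def test_low_vaf_everywhere_retained(self):
        v = variant_rows([("chrA", 100, "S1", 10, 100), ("chrA", 100, "S2", 10, 100)])
        segs = {s: segments_for({"chrA": 2}) for s in ("S1", "S2")}
        rows, excl = prepare_clonal_inputs(v, {"S1": 0.25, "S2": 0.8}, segs)
        assert len(rows) == 2 and excl.empty

    def test_exclusion_log_partitions_input(self):
        v = variant_rows([("chrA", 100, "S1", 35, 100), ("chrB", 200, "S1", 10, 100),
                          ("chrC", 300, "S1", 10, 100)])
        v2 = v.copy(); v2["sample_id"] = "S2"
        both = pd.concat([v, v2], ignore_index=True)
        segs = {s: segments_for({"chrA": 2, "chrB": 0, "chrC": 2}) for s in ("S1", "S2")}
        rows, excl = prepare_clonal_inputs(both, {"S1": 0.2, "S2": 0.9}, segs)
        n_variants = both["pos"].nunique()
        assert rows["key"].nunique() + len(excl) == n_variants

    def test_missing_segments_errors(self):
        v = variant_rows([("chrA", 100, "S1", 10, 100)])
        with pytest.raises(ValueError, match="segment"):
            prepare_clonal_inputs(v, {"S1": 0.5}, {})

    def test_absent_sample_rows_filled_with_zero_alt(self):
        v = variant_rows([("chrA", 100, "S1", 30, 100),
                          ("chrB", 200, "S1", 20, 100), ("chrB", 200, "S2", 20, 100)])
        segs = {s: segments_for({"chrA": 2, "chrB": 2}) for s in ("S1", "S2")}
        rows, _ = prepare_clonal_inputs(v, {"S1": 0.8, "S2": 0.8}, segs)
        filled = rows[(rows["chrom"] == "chrA") & (rows["sample_id"] == "S2")]
        assert len(filled) == 1 and filled["alt_count"].iloc[0] == 0


class TestClusterCcf:
    def make_ccfs(self, centers, n_per, noise, seed):
        rng = np.random.default_rng(seed)
        data = {}
        for ci, c in enumerate(centers):
            for vi in range(n_per):
                data[f"c{ci}v{vi}"] = np.clip(np.asarray(c) + rng.normal(0, noise, len(c)), 0, 1)
        return pd.DataFrame(data, index=["s1", "s2"]).T

    def test_two_well_separated_clusters(self):
        ccfs = self.make_ccfs([(1, 1), (0.2, 0.5)], 10, 0.02, 0)
        clusters = cluster_ccf(ccfs, seed=0)
        assert len(clusters) == 2
        top = clusters[0]
        assert top.ccf_per_sample["s1"] == pytest.approx(1.0, abs=0.05)

    def test_identical_ccfs_single_cluster(self):
        ccfs = self.make_ccfs([(0.6, 0.6)], 12, 0.0, 0)
        assert len(cluster_ccf(ccfs, seed=0)) == 1

    def test_deterministic_given_seed(self):
        ccfs = self.make_ccfs([(1, 1), (0.3, 0.6), (0.6, 0.2)], 8, 0.05, 3)
        a = cluster_ccf(ccfs, seed=4)
        b = cluster_ccf(ccfs, seed=4)
        assert [c.members for c in a] == [c.members for c in b]
        assert [c.ccf_per_sample for c in a] == [c.ccf_per_sample for c in b]

    def test_every_variant_in_exactly_one_cluster(self):
        ccfs = self.make_ccfs([(1, 1), (0.3, 0.6)], 9, 0.04, 5)
        clusters = cluster_ccf(ccfs, seed=0)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(ccfs.index)


class TestPrevalenceShifts:
    def clusters(self, ccf_a, ccf_b):
        return [ClonalCluster(0, ["v1"], {"s1": ccf_a, "s2": ccf_b})]

    def test_shift_above_threshold_flagged(self):
        out = detect_prevalence_shifts(self.clusters(0.40, 0.55), ["s1", "s2"])
        assert out.loc[0, "flagged"] and out.loc[0, "delta_ccf"] == pytest.approx(0.15)

    def test_boundary_shift_not_flagged(self):
        out = detect_prevalence_shifts(self.clusters(0.40, 0.50), ["s1", "s2"])
        assert not out.loc[0, "flagged"]

    def test_decrease_flagged_symmetrically(self):
        out = detect_prevalence_shifts(self.clusters(0.55, 0.40), ["s1", "s2"])
        assert out.loc[0, "flagged"]

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            detect_prevalence_shifts(self.clusters(0.5, 0.5), ["s1"])


class TestUnrepresentedClone:
    def test_warning_when_anchor_cn0_excluded(self):
        excl = pd.DataFrame([{"key": "chr17:7577539:G:A", "reason": "cn0"}])
        w = unrepresented_clone_warning(excl, "chr17:7577539:G:A")
        assert w is not None and "high-frequency" in w["warning"]

    def test_no_warning_otherwise(self):
        excl = pd.DataFrame([{"key": "chr1:1:A:T", "reason": "cn0"}])
        assert unrepresented_clone_warning(excl, "chr17:7577539:G:A") is None
        assert unrepresented_clone_warning(pd.DataFrame(columns=["key", "reason"]),
                                           "chr17:7577539:G:A") is None
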