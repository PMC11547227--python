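"""Table I/O: coordinate conventions, validation, round trips."""

import numpy as np
import pandas as pd
import pytest

from ascites_cfdna import formats


@pytest.fixture
def tsv_variants(tmp_path):
    path = tmp_path / "v.tsv"
    path.write_text(
        "chrom\tpos\tref\talt\talt_count\tdepth\taf_gnomad_exome\n"
        "chr17\t7577539\tG\tA\t120\t400\t0.0001\n"
        "chr1\t1000\tC\tT\t5\t0\t\n"  # depth 0 -> dropped
        "chr2\t500\tA\tG\t10\t100\t0.2\n"
    )
    return path


class TestVariantTables:
    def test_tsv_vaf_computed_and_depth0_dropped(self, tsv_variants):
        df = formats.read_variants(tsv_variants, dialect="TSV", sample_id="S1")
        assert len(df) == 2
        assert df.attrs["n_dropped_depth0"] == 1
        assert df.loc[df["pos"] == 7577539, "vaf"].iloc[0] == pytest.approx(0.30)
        assert (df["sample_id"] == "S1").all()

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\tref\talt\talt_count\tdepth\n"
                        "chr1\t100\tA\tT\t5\t50\n"
                        "chr1\toops\tA\tT\t5\t50\n")
        with pytest.raises(formats.FormatError, match="line 3"):
            formats.read_variants(path, dialect="TSV")

    def test_vcf_ad_parsing(self, tmp_path):
        path = tmp_path / "v.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GNOMAD_EXOME_AF,Number=1,Type=Float,Description="x">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="x">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr17\t7577539\t.\tG\tA\t.\tPASS\tGNOMAD_EXOME_AF=0.0001;GENE=TP53\tAD\t70,30\n"
        )
        df = formats.read_variants(path, dialect="VCF")
        assert df.loc[0, "alt_count"] == 30
        assert df.loc[0, "depth"] == 100
        assert df.loc[0, "vaf"] == pytest.approx(0.30)
        assert df.loc[0, "gene"] == "TP53"
        assert df.loc[0, "af_gnomad_exome"] == pytest.approx(1e-4)

    def test_roundtrip_full_precision(self, tsv_variants, tmp_path):
        df = formats.read_variants(tsv_variants, dialect="TSV")
        out = tmp_path / "out.tsv"
        formats.write_variants(df, out)
        back = formats.read_variants(out, dialect="TSV")
        pd.testing.assert_frame_equal(
            back[["chrom", "pos", "ref", "alt", "alt_count", "depth", "vaf"]],
            df[["chrom", "pos", "ref", "alt", "alt_count", "depth", "vaf"]],
        )


class TestBinSegmentTables:
    def test_cnr_parse(self, tmp_path):
        path = tmp_path / "s.cnr"
        path.write_text("chromosome\tstart\tend\tlog2\tdepth\tweight\n"
                        "chr8\t1000\t101000\t0.58\t610\t0.9\n")
        df = formats.read_bins(path)
        assert (df["end"] - df["start"]).iloc[0] == 100000
        assert df["log2"].iloc[0] == pytest.approx(0.58)

    def test_unsorted_input_sorted_with_warning(self, tmp_path, caplog):
        path = tmp_path / "s.cnr"
        path.write_text("chromosome\tstart\tend\tlog2\n"
                        "chr1\t5000\t6000\t0.1\nchr1\t0\t1000\t0.2\n")
        with caplog.at_level("WARNING"):
            df = formats.read_bins(path)
        assert list(df["start"]) == [0, 5000]
        assert any("unsorted" in r.message for r in caplog.records)

    def test_overlapping_segments_error(self, tmp_path):
        path = tmp_path / "s.cns"
        path.write_text("chromosome\tstart\tend\tlog2\n"
                        "chr1\t0\t10\t0.0\nchr1\t5\t20\t0.0\n")
        with pytest.raises(formats.FormatError, match="overlap"):
            formats.read_segments(path)

    def test_start_ge_end_rejected(self, tmp_path):
        path = tmp_path / "s.cns"
        path.write_text("chromosome\tstart\tend\tlog2\nchr1\t10\t10\t0.0\n")
        with pytest.raises(formats.FormatError):
            formats.read_segments(path)


class TestCoordinates:
    @pytest.mark.parametrize("pos,expected", [(1, 0), (100_000, 0), (100_001, 1)])
    def test_one_based_position_to_bin(self, pos, expected):
        assert formats.bin_index(pos, 100_000) == expected

    def test_bin_index_vectorised(self):
        idx = formats.bin_index(np.array([1, 100_000, 100_001]), 100_000)
        assert list(idx) == [0, 0, 1]


class TestManifest:
    def make(self, **kw):
        df = pd.DataFrame({
            "participant_id": ["P1", "P1"], "sample_id": ["S1", "S2"],
            "specimen": ["cfDNA", "cfDNA"], "timepoint_days": [0, 30],
        })
        for k, v in kw.items():
            df[k] = v
        return df

    def test_valid(self):
        assert len(formats.validate_manifest(self.make())) == 2

    def test_duplicate_sample_rejected(self):
        with pytest.raises(formats.FormatError, match="duplicate"):
            formats.validate_manifest(self.make(sample_id=["S1", "S1"]))

    def test_unknown_specimen_rejected(self):
        with pytest.raises(formats.FormatError, match="specimen"):
            formats.validate_manifest(self.make(specimen=["cfDNA", "serum"]))

    def test_initial_samples_picks_min_timepoint(self):
        m = self.make()
        init = formats.initial_samples(m)
        assert list(init["sample_id"]) == ["S1"]


class TestPycloneExport:
    def variants(self):
        rows = []
        for sid in ("S1", "S2"):
            for i in range(3):
                rows.append({"chrom": "chr1", "pos": 100 + i, "ref": "A", "alt": "T",
                             "sample_id": sid, "alt_count": 30, "depth": 100,
                             "cn_tumour": 2})
        return pd.DataFrame(rows)

    def test_rows_and_diploid_normal(self, tmp_path):
        out = formats.write_pyclone_input(
            self.variants(), {"S1": 0.8, "S2": 0.5}, tmp_path / "p.tsv")
        assert len(out) == 6
        assert (out["normal_cn"] == 2).all()
        assert (out["ref_counts"] == 70).all()
        assert set(out["tumour_content"]) == {0.8, 0.5}

    def test_major_minor_split(self, tmp_path):
        v = self.variants().iloc[:1].assign(cn_tumour=3)
        out = formats.write_pyclone_input(v, {"S1": 0.8}, tmp_path / "p.tsv")
        assert out.loc[0, "major_cn"] == 2 and out.loc[0, "minor_cn"] == 1
        v1 = self.variants().iloc[:1].assign(cn_tumour=1)
        out1 = formats.write_pyclone_input(v1, {"S1": 0.8}, tmp_path / "p.tsv")
        assert out1.loc[0, "major_cn"] == 1 and out1.loc[0, "minor_cn"] == 0

    def test_missing_purity_errors(self, tmp_path):
        with pytest.raises(formats.FormatError, match="purity"):
            formats.write_pyclone_input(self.variants(), {"S1": 0.8}, tmp_path / "p.tsv")
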