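"""Feature tables, modProb byte encoding, MM/ML alignments, annotations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import permod
from permod.errors import (
    ConsistencyError,
    FormatError,
    TagConsistencyError,
    ValidationError,
)
from permod.feature_io import (
    FEATURES_RNA002,
    FEATURES_RNA004,
    Transcript,
    read_bedmethyl,
    read_isoform_table,
    read_polya_table,
    write_feature_table,
)
from tests.conftest import REF_NAME


def _rna002_frame(n=10):
    rng = np.random.default_rng(0)
    tr = rng.uniform(0.5, 1.0, n)
    rest = (1 - tr)[:, None] * rng.dirichlet(np.ones(3), n)
    return pd.DataFrame({
        "read_id": [f"r{i}" for i in range(n)],
        "ref_id": "ref1", "pos": 10, "strand": "+", "ref_base": "A",
        "kmer": "CCTAGCA", "sample": "control",
        "SI": rng.normal(80, 4, n), "MP": rng.uniform(0, 1, n),
        "DT": rng.uniform(1, 20, n), "DT10": rng.uniform(1, 20, n),
        "TR": tr, "TA": tr, "TC": rest[:, 0], "TG": rest[:, 1], "TT": rest[:, 2],
    })


class TestFeatureTable:
    def test_roundtrip_rna002(self, tmp_path):
        path = tmp_path / "feat.tsv"
        write_feature_table(_rna002_frame(10), path)
        df = permod.read_feature_table(path, mode="rna002")
        assert len(df) == 10
        assert all(c in df.columns for c in FEATURES_RNA002)
        assert len(FEATURES_RNA002) == 9

    def test_header_only_is_empty_stream(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_feature_table(_rna002_frame(0), path)
        df = permod.read_feature_table(path)
        assert len(df) == 0

    def test_probability_bound_violation_names_line(self, tmp_path):
        frame = _rna002_frame(5)
        frame.loc[2, "TR"] = 1.2
        path = tmp_path / "bad.tsv"
        write_feature_table(frame, path)
        with pytest.raises(ValidationError, match="line 4.*TR"):
            permod.read_feature_table(path)

    def test_skip_mode_rejects_only_bad_rows(self, tmp_path):
        frame = _rna002_frame(8)
        frame.loc[1, "MP"] = -0.5
        frame.loc[5, "DT"] = -1.0
        path = tmp_path / "mixed.tsv"
        write_feature_table(frame, path)
        df = permod.read_feature_table(path, on_bad="skip")
        assert len(df) == 6  # count conservation: 8 data lines - 2 rejected
        assert [ln for ln, _ in df.attrs["rejected"]] == [3, 7]

    def test_missing_column_is_format_error(self, tmp_path):
        frame = _rna002_frame(3).drop(columns=["DT10"])
        path = tmp_path / "short.tsv"
        write_feature_table(frame, path)
        with pytest.raises(FormatError, match="DT10"):
            permod.read_feature_table(path)

    def test_rna004_schema_width(self):
        assert len(FEATURES_RNA004) == 39


class TestModProbEncoding:
    @pytest.mark.parametrize("p,byte,decoded", [
        (0.0, 0, 0.001953125),
        (1.0, 255, 0.998046875),
        (0.5, 128, 0.501953125),
    ])
    def test_fixed_points(self, p, byte, decoded):
        assert permod.encode_modprob(p) == byte
        assert permod.decode_modprob(byte) == pytest.approx(decoded, abs=1e-12)
        assert abs(p - permod.decode_modprob(permod.encode_modprob(p))) <= 1 / 256

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_roundtrip_bound(self, p):
        assert abs(p - permod.decode_modprob(permod.encode_modprob(p))) <= 1 / 256

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            permod.encode_modprob(1.5)
        with pytest.raises(ValueError):
            permod.decode_modprob(300)


class TestModBam:
    def test_counts_and_delta_expansion(self, sam_factory):
        # MM deltas 0,2 over the A's of the read: calls at the 1st A and,
        # skipping two A's, the 4th A (query positions 1 and 10)
        seq = "CAACCTAACCAACC"
        path = sam_factory([{
            "query_name": "r1", "seq": seq, "ref_start": 2,
            "mm": "A+a?,0,2;", "ml": [200, 100],
        }])
        calls = permod.read_modbam(path)
        assert len(calls) == 2
        a_positions = [i for i, b in enumerate(seq) if b == "A"]
        assert list(calls["pos"]) == [2 + a_positions[0], 2 + a_positions[3]]
        assert calls["mod_prob"].tolist() == [
            permod.decode_modprob(200), permod.decode_modprob(100)]

    def test_reverse_strand_reported_in_reference_coordinates(self, sam_factory):
        # stored sequence is the reverse complement; original read AACCG has
        # A's at original positions 0 and 1
        path = sam_factory([{
            "query_name": "r2", "seq": "CGGTT", "ref_start": 5,
            "is_reverse": True, "mm": "A+a?,0,0;", "ml": [250, 10],
        }])
        calls = permod.read_modbam(path)
        assert list(calls["strand"]) == ["-", "-"]
        assert set(calls["base"]) == {"A"}
        # original position 0 is the last stored base -> reference 5+4
        assert sorted(calls["pos"]) == [8, 9]

    def test_mm_without_matching_ml_is_error(self, sam_factory):
        path = sam_factory([{
            "query_name": "r3", "seq": "CAACC", "ref_start": 0,
            "mm": "A+a?,0,1;", "ml": [100],
        }])
        with pytest.raises(TagConsistencyError):
            permod.read_modbam(path)

    def test_unmapped_reads_skipped_with_counter(self, sam_factory):
        path = sam_factory([
            {"query_name": "r4", "seq": "CAACC", "ref_start": 0,
             "mm": "A+a?,0;", "ml": [77]},
            {"query_name": "r5", "seq": "CAACC", "ref_start": 0, "unmapped": True},
        ])
        calls = permod.read_modbam(path)
        assert len(calls) == 1
        assert calls.attrs["skipped_unmapped"] == 1

    def test_write_read_roundtrip(self, sam_factory, tmp_path):
        rng = np.random.default_rng(42)
        seq_f = "CAACCTAACCAACCTAACCA"
        seq_r = "TTGGTTAGGTTGGT"  # original = ACCAACCTAACCAA
        template = sam_factory([
            {"query_name": "fwd", "seq": seq_f, "ref_start": 0},
            {"query_name": "rev", "seq": seq_r, "ref_start": 40,
             "is_reverse": True},
        ], name="template.sam")
        rows = []
        for i, b in enumerate(seq_f):
            if b == "A":
                rows.append(("fwd", REF_NAME, i, "+", rng.uniform()))
        for i, b in enumerate(seq_r):
            if b == "T":  # a sense-strand A of the reverse read
                rows.append(("rev", REF_NAME, 40 + i, "-", rng.uniform()))
        calls = pd.DataFrame(rows, columns=["read_id", "ref_id", "pos",
                                            "strand", "mod_prob"])
        out = tmp_path / "out.sam"
        permod.write_modbam(calls, template, out)
        back = permod.read_modbam(out)
        merged = calls.merge(back, on=["read_id", "pos"], suffixes=("", "_rt"))
        assert len(merged) == len(calls)  # identity on coordinates
        assert (merged["mod_prob"] - merged["mod_prob_rt"]).abs().max() <= 1 / 256

    def test_call_at_unaligned_position_is_error(self, sam_factory, tmp_path):
        template = sam_factory([
            {"query_name": "fwd", "seq": "CAACC", "ref_start": 0}])
        calls = pd.DataFrame([("fwd", REF_NAME, 99, "+", 0.9)],
                             columns=["read_id", "ref_id", "pos", "strand",
                                      "mod_prob"])
        with pytest.raises(ConsistencyError):
            permod.write_modbam(calls, template, tmp_path / "x.sam")


class TestBedMethyl:
    def test_frequency_formatting(self, tmp_path):
        sites = pd.DataFrame([{
            "chrom": "chr1", "pos": 100, "strand": "+",
            "coverage": 25, "n_modified": 2,
        }])
        path = tmp_path / "sites.bed"
        permod.write_bedmethyl(sites, path)
        fields = path.read_text().strip().split("\t")
        assert fields[:6] == ["chr1", "100", "101", "a", "25", "+"]
        assert fields[8] == "0,0,0"
        assert fields[9] == "25"
        assert fields[10] == "8.0"

    def test_coverage_capped_at_1000_in_score_column(self, tmp_path):
        sites = pd.DataFrame([{"chrom": "c", "pos": 0, "strand": "+",
                               "coverage": 4000, "n_modified": 400}])
        path = tmp_path / "big.bed"
        permod.write_bedmethyl(sites, path)
        fields = path.read_text().strip().split("\t")
        assert fields[4] == "1000" and fields[9] == "4000"

    def test_empty_set_writes_empty_file(self, tmp_path):
        path = tmp_path / "empty.bed"
        permod.write_bedmethyl(pd.DataFrame(
            columns=["chrom", "pos", "strand", "coverage", "n_modified"]), path)
        assert path.read_text() == ""

    def test_read_back(self, tmp_path):
        sites = pd.DataFrame([{"chrom": "chr1", "pos": 5, "strand": "-",
                               "coverage": 50, "n_modified": 10}])
        path = tmp_path / "rt.bed"
        permod.write_bedmethyl(sites, path)
        back = read_bedmethyl(path)
        assert back.loc[0, "coverage"] == 50
        assert back.loc[0, "n_modified"] == 10


class TestExonAnnotation:
    def test_gff3_coordinates_converted(self, tmp_path):
        gff = tmp_path / "anno.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t101\t500\t.\t+\t.\tID=tx1;Parent=gene1\n"
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=tx1\n"
            "chr1\tsrc\texon\t301\t500\t.\t+\t.\tParent=tx1\n"
        )
        anno = permod.read_exon_annotation(gff)
        assert anno["tx1"].exons == [(100, 200), (300, 500)]
        assert anno["tx1"].gene_id == "gene1"

    def test_bed12_blocks(self, tmp_path):
        bed = tmp_path / "anno.bed"
        bed.write_text("chr1\t100\t500\ttx2\t0\t+\t100\t500\t0\t2\t50,100\t0,300\n")
        anno = permod.read_exon_annotation(bed)
        assert anno["tx2"].exons == [(100, 150), (400, 500)]

    def test_overlapping_exons_rejected(self):
        tr = Transcript("t", "g", "+", [(0, 100), (50, 150)])
        with pytest.raises(ValidationError):
            tr.validate()


class TestAuxTables:
    def test_polya_validation(self, tmp_path):
        path = tmp_path / "pa.tsv"
        pd.DataFrame({"read_id": ["a"], "polya_length": [-3]}).to_csv(
            path, sep="\t", index=False)
        with pytest.raises(ValidationError):
            read_polya_table(path)

    def test_isoform_one_assignment_per_read(self, tmp_path):
        path = tmp_path / "iso.tsv"
        pd.DataFrame({"read_id": ["a", "a"], "transcript_id": ["t1", "t2"],
                      "class": ["unique", "fsm"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError):
            read_isoform_table(path)
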