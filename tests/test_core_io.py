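"""Domain types, normalization, and file round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitofinish import DepthTrack, Feature, NucSequence
from mitofinish.core import normalize_residues, revcomp
from mitofinish.io import (
    read_depth,
    read_fasta,
    read_fastq,
    read_features,
    write_fasta,
    write_features,
    write_fastq,
)


class TestNormalization:
    def test_lowercase_uppercased(self):
        assert normalize_residues("acgt") == ("ACGT", 0)

    def test_ambiguity_demoted_to_n_with_count(self):
        assert normalize_residues("ACRT") == ("ACNT", 1)
        assert normalize_residues("RYSWKMBDHV") == ("N" * 10, 10)

    def test_gap_characters_rejected(self):
        with pytest.raises(ValueError, match="illegal residue"):
            normalize_residues("AC-GT")

    @given(st.text(alphabet="ACGTNacgtRYSWKMBDHVryswkmbdhv", max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent(self, raw):
        once, _ = normalize_residues(raw)
        twice, n = normalize_residues(once)
        assert twice == once and n == 0


class TestTypes:
    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            NucSequence("x", "")

    def test_read_quality_length_mismatch(self):
        from mitofinish import Read

        with pytest.raises(ValueError, match="qualities"):
            Read("r", "ACGT", (30, 30))

    def test_feature_interval_validation(self):
        with pytest.raises(ValueError, match="end"):
            Feature("s", "g", "CDS", 10, 5, "+")
        # wrap form requires start > end
        f = Feature("s", "g", "CDS", 10, 5, "+", wrap=True)
        assert f.length(20) == 15

    def test_wrap_feature_extraction(self):
        seq = NucSequence("s", "AAACCCGGGTTT", "circular")
        f = Feature("s", "g", "tRNA", 9, 3, "+", wrap=True)
        assert f.extract(seq) == "TTTAAA"
        fr = Feature("s", "g", "tRNA", 9, 3, "-", wrap=True)
        assert fr.extract(seq) == revcomp("TTTAAA")

    def test_depth_rejects_negative(self):
        with pytest.raises(ValueError):
            DepthTrack("s", (1, -1))


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n")
        (seq,) = read_fasta(p)
        assert seq.id == "a" and seq.residues == "ACGT" and seq.topology == "linear"

    def test_alignment_characters_rejected(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">a\nacgt\n>b\nAC-GT\n")
        with pytest.raises(ValueError, match="'b'"):
            read_fasta(p)

    def test_ambiguity_normalized(self, tmp_path):
        p = tmp_path / "amb.fa"
        p.write_text(">a\nACRT\n")
        (seq,) = read_fasta(p)
        assert seq.residues == "ACNT"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(ValueError, match="duplicate.*'a'"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA"):
            read_fasta(p)

    def test_round_trip_and_wrapping(self, tmp_path):
        seqs = [NucSequence("x", "ACGT" * 60), NucSequence("y", "A" * 150)]
        p = tmp_path / "rt.fa"
        write_fasta(seqs, p, line_width=70)
        assert read_fasta(p) == seqs
        lines = p.read_text().splitlines()
        # 240 bases -> 4 lines, 150 bases -> 3 lines at width 70
        assert len([l for l in lines if not l.startswith(">")]) == 7

    def test_line_wrapping_count(self, tmp_path):
        p = tmp_path / "w.fa"
        write_fasta([NucSequence("y", "A" * 150)], p, line_width=70)
        body = [l for l in p.read_text().splitlines() if not l.startswith(">")]
        assert len(body) == 3

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_fasta([], tmp_path / "e.fa")


class TestFastq:
    def test_round_trip(self, tmp_path):
        from mitofinish import Read

        reads = [Read("r1", "ACGT", (10, 20, 30, 40))]
        p = tmp_path / "r.fq"
        write_fastq(reads, p)
        assert read_fastq(p) == reads


class TestFeatures:
    def test_gff3_coordinate_conversion(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chrM\tsrc\ttRNA\t1\t3\t.\t+\t.\tID=t1;Name=trnM\n"
            "chrM\tsrc\tCDS\t5\t10\t.\t-\t.\tID=c1;Name=cox1\n"
        )
        feats = read_features(p)
        assert feats[0].start == 0 and feats[0].end == 3
        assert feats[1] == Feature("chrM", "cox1", "CDS", 4, 10, "-")

    def test_tsv_is_identity(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "seq_id\tname\tftype\tstart\tend\tstrand\ttransl_table\twrap\n"
            "chrM\tcox1\tCDS\t0\t3\t+\t5\tfalse\n"
        )
        (f,) = read_features(p)
        assert (f.start, f.end) == (0, 3)

    def test_unknown_type_names_line(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("chrM\tsrc\texon\t1\t3\t.\t+\t.\tID=x\n")
        with pytest.raises(ValueError, match="exon"):
            read_features(p)

    def test_bad_strand_rejected(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("chrM\tsrc\tCDS\t1\t3\t.\t*\t.\tID=x\n")
        with pytest.raises(ValueError, match="strand"):
            read_features(p)

    def test_gff3_round_trip(self, tmp_path):
        feats = [
            Feature("chrM", "cox1", "CDS", 4, 10, "-"),
            Feature("chrM", "trnM", "tRNA", 0, 3, "+"),
        ]
        p = tmp_path / "rt.gff3"
        write_features(feats, p)
        assert read_features(p) == feats

    def test_tsv_round_trip_keeps_wrap(self, tmp_path):
        feats = [Feature("chrM", "nad1", "CDS", 14900, 120, "+", wrap=True)]
        p = tmp_path / "rt.tsv"
        write_features(feats, p)
        assert read_features(p) == feats


class TestDepth:
    def test_run_expansion(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s\t0\t5\t10\ns\t5\t8\t2\n")
        track = read_depth(p, length=8)
        assert track.depth == (10, 10, 10, 10, 10, 2, 2, 2)

    def test_uncovered_positions_are_zero(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s\t0\t3\t7\ns\t5\t6\t4\n")
        track = read_depth(p, length=6)
        assert track.depth == (7, 7, 7, 0, 0, 4)

    def test_out_of_bounds_run_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s\t0\t10\t7\n")
        with pytest.raises(ValueError, match="exceeds"):
            read_depth(p, length=8)

    def test_conflicting_overlap_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s\t0\t5\t10\ns\t3\t6\t2\n")
        with pytest.raises(ValueError, match="conflicting"):
            read_depth(p, length=8)

    def test_per_base_rows(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s\t0\t9\ns\t2\t4\n")
        assert read_depth(p, length=3).depth == (9, 0, 4)
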