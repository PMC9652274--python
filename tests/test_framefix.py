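"""Premature-stop detection and homopolymer frameshift repair."""

import pytest

from mitofinish import (
    Feature,
    NucSequence,
    correct_frameshifts,
    find_candidate_homopolymers,
    find_premature_stops,
    inject_homopolymer_deletions,
    make_genome,
    shift_features,
)
from mitofinish.core import revcomp


def _cds_seq(body: str, seq_id="s"):
    """Wrap a plus-strand CDS string into (sequence, feature)."""
    seq = NucSequence(seq_id, body)
    return seq, Feature(seq_id, "g", "CDS", 0, len(body), "+")


class TestPrematureStops:
    def test_clean_orf_has_none(self):
        seq, cds = _cds_seq("ATGAAATTTTAA")
        assert find_premature_stops(seq, cds) == []

    def test_single_deletion_shifts_frame_into_stop(self):
        # truth ATG AAA ATA AGC TAA loses one A from its AAAA run; the
        # shifted frame then reads ATG AAA TAA ... -> stop at codon 2
        seq, cds = _cds_seq("ATGAAATAAGCTAA")
        stops = find_premature_stops(seq, cds)
        assert stops == [2]

    def test_minus_strand_matches_plus_twin(self):
        body = "ATGAAATAAGCTAA"
        plus_seq, plus_cds = _cds_seq(body)
        minus_seq = NucSequence("s", revcomp(body))
        minus_cds = Feature("s", "g", "CDS", 0, len(body), "-")
        assert find_premature_stops(minus_seq, minus_cds) == find_premature_stops(
            plus_seq, plus_cds
        )

    def test_short_cds_rejected(self):
        seq, _ = _cds_seq("ATGAAATTTTAA")
        tiny = Feature("s", "g", "CDS", 0, 5, "+", wrap=False)
        with pytest.raises(ValueError, match="shorter"):
            find_premature_stops(seq, tiny)

    def test_terminal_stop_not_reported(self):
        seq, cds = _cds_seq("ATGAAATTTTAA")
        assert 3 not in find_premature_stops(seq, cds)


class TestCandidates:
    def test_single_run_found(self):
        body = "ATG" + "GCC" * 5 + "A" * 9 + "GCC" * 10 + "TAATAA"
        seq, cds = _cds_seq(body)
        (stop,) = find_premature_stops(seq, cds)
        runs = find_candidate_homopolymers(seq, cds, stop)
        assert len(runs) == 1 and runs[0][1] == 9 and runs[0][2] == "A"

    def test_nearest_to_stop_first(self):
        # T-run far from the stop, A-run near it
        body = "ATG" + "T" * 9 + "GCC" * 12 + "A" * 9 + "GCC" * 3 + "TAGTAA"
        seq, cds = _cds_seq(body)
        (stop,) = find_premature_stops(seq, cds)
        runs = find_candidate_homopolymers(seq, cds, stop)
        assert [r[2] for r in runs] == ["A", "T"]

    def test_below_threshold_empty(self):
        body = "ATG" + "A" * 7 + "GC" + "GCC" * 10 + "TAGTAA"
        seq, cds = _cds_seq(body)
        stops = find_premature_stops(seq, cds)
        assert find_candidate_homopolymers(seq, cds, stops[0], min_run=8) == []


class TestShiftFeatures:
    @pytest.mark.parametrize(
        "interval,pos,expected",
        [((100, 200), 150, (100, 201)), ((100, 200), 250, (100, 200)),
         ((300, 400), 150, (301, 401)), ((100, 200), 100, (101, 201)),
         ((100, 200), 200, (100, 200))],
    )
    def test_boundary_semantics(self, interval, pos, expected):
        f = Feature("s", "g", "CDS", *interval, "+")
        (out,) = shift_features([f], pos, 1)
        assert (out.start, out.end) == expected

    def test_order_preserved(self):
        feats = [
            Feature("s", "a", "tRNA", 0, 60, "+"),
            Feature("s", "b", "CDS", 100, 400, "+"),
        ]
        out = shift_features(feats, 50, 1)
        assert [f.name for f in out] == ["a", "b"]


class TestCorrection:
    def test_simulator_truth_recovered(self):
        genome, feats = make_genome(seed=31)
        mut, edits, mut_feats = inject_homopolymer_deletions(
            genome, feats, n=4, seed=32
        )
        fixed, fixed_feats, reports = correct_frameshifts(mut, mut_feats)
        assert fixed.residues == genome.residues
        assert fixed_feats == feats
        touched = {e.gene for e in edits}
        by_gene = {r.gene: r for r in reports}
        for g in touched:
            assert by_gene[g].resolved and len(by_gene[g].edits) == 1
            assert by_gene[g].edits[0].reason == "homopolymer-frameshift"

    def test_clean_genome_untouched(self):
        genome, feats = make_genome(seed=33)
        fixed, out_feats, reports = correct_frameshifts(genome, feats)
        assert fixed.residues == genome.residues
        assert out_feats == feats
        assert all(not r.edits for r in reports)

    def test_short_run_corrected_via_fallback(self):
        # deletion planted in a 4-A run: only the fallback tier (run > 2)
        # can find it
        body = "ATG" + "GCC" * 4 + "AAAACC" + "CTAACC" + "GTC" * 5 + "TAA"
        truth, cds = _cds_seq(body)
        mut = NucSequence("s", body[:17] + body[18:])  # delete one A
        mut_cds = Feature("s", "g", "CDS", 0, len(body) - 1, "+")
        assert find_premature_stops(mut, mut_cds)
        fixed, _, reports = correct_frameshifts(mut, [mut_cds])
        assert reports[0].resolved
        assert reports[0].edits[0].run_len_before == 3
        assert fixed.residues == truth.residues

    def test_length_conservation_and_no_regression(self):
        genome, feats = make_genome(seed=34)
        mut, edits, mut_feats = inject_homopolymer_deletions(genome, feats, n=5, seed=35)
        before = {
            f.name: len(find_premature_stops(mut, f))
            for f in mut_feats
            if f.ftype == "CDS"
        }
        fixed, fixed_feats, reports = correct_frameshifts(mut, mut_feats)
        n_edits = sum(len(r.edits) for r in reports)
        assert len(fixed) == len(mut) + n_edits
        for f in fixed_feats:
            if f.ftype == "CDS":
                assert len(find_premature_stops(fixed, f)) <= before[f.name]

    def test_no_cds_rejected(self):
        genome, feats = make_genome(seed=36)
        trnas = [f for f in feats if f.ftype == "tRNA"]
        with pytest.raises(ValueError, match="no CDS"):
            correct_frameshifts(genome, trnas)
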