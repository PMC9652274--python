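"""Anchored alignment vs full-DP oracle, diff classification, accuracy."""

import numpy as np
import pytest
from Bio import Align

from mitofinish import (
    NucSequence,
    accuracy,
    align_assemblies,
    classify_differences,
    compare_assemblies,
    error_profile,
    make_genome,
)
from mitofinish.concordance import (
    DivergentSequencesError,
    gotoh_align,
    synchronized_query,
)
from mitofinish.core import revcomp
from mitofinish.coverage import MaskSet


def _oracle_aligner():
    """Independent full-DP oracle: Biopython's exhaustive global aligner
    under the same scoring (gap run of length L costs 4 + L)."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5
    al.extend_gap_score = -1
    return al


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, s, rate):
    out = []
    for ch in s:
        r = rng.random()
        if r < rate * 0.5:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        elif r < rate * 0.75:
            continue
        elif r < rate:
            out.extend([ch, rng.choice(list("ACGT"))])
        else:
            out.append(ch)
    return "".join(out)


class TestGotoh:
    def test_score_matches_library_dp(self):
        rng = np.random.default_rng(1)
        oracle = _oracle_aligner()
        for _ in range(30):
            a = _rand_seq(rng, int(rng.integers(20, 150)))
            b = _mutate(rng, a, 0.1)
            score, ops = gotoh_align(a, b)
            assert score == oracle.align(a, b).score
            # ops must replay to the two input lengths
            assert sum(n for op, n in ops if op in "=XD") == len(a)
            assert sum(n for op, n in ops if op in "=XI") == len(b)


class TestAlign:
    def test_identity_of_self(self):
        g, _ = make_genome(seed=41)
        aln = align_assemblies(g, g)
        assert aln.total_diff_bases == 0 and aln.ops == (("=", len(g)),)

    def test_rotation_and_revcomp_synchronized(self):
        g, _ = make_genome(seed=42)
        q = NucSequence("q", revcomp(g.rotated(8123).residues), "circular")
        aln = align_assemblies(g, q)
        assert aln.total_diff_bases == 0
        assert aln.query_strand == "-"

    def test_planted_deletion_single_gap(self):
        g, _ = make_genome(seed=43)
        q = NucSequence("q", g.residues[:6000] + g.residues[6009:], "circular")
        aln = align_assemblies(g, q)
        gaps = [(op, n) for op, n in aln.ops if op != "="]
        assert gaps == [("D", 9)]

    def test_unrelated_sequences_rejected(self):
        rng = np.random.default_rng(44)
        a = NucSequence("a", _rand_seq(rng, 2000))
        b = NucSequence("b", _rand_seq(rng, 2000))
        with pytest.raises(DivergentSequencesError):
            align_assemblies(a, b, circular=False)

    def test_oracle_equivalence_random_pairs(self):
        """Anchored diff-base count equals the exhaustive full-DP count."""
        rng = np.random.default_rng(45)
        oracle = _oracle_aligner()
        for _ in range(40):
            a = _rand_seq(rng, int(rng.integers(100, 301)))
            b = _mutate(rng, a, 0.05)
            aln = align_assemblies(NucSequence("a", a), NucSequence("b", b), circular=False)
            best = oracle.align(a, b)[0]
            d_oracle = sum(1 for x, y in zip(best[0], best[1]) if x != y)
            assert aln.total_diff_bases == d_oracle


class TestClassification:
    def test_single_base_deletion_in_a_run_is_homopolymer(self):
        rng = np.random.default_rng(51)
        res = _rand_seq(rng, 100) + "CAAAAT" + _rand_seq(rng, 100)
        ref = NucSequence("r", res)
        # delete one A from the CAAAAT context (run of 4 > 2)
        q = NucSequence("q", res[:102] + res[103:])
        aln = align_assemblies(ref, q, circular=False)
        diffs = classify_differences(aln, ref, q)
        assert len(diffs) == 1
        assert diffs[0].dtype == "deletion" and diffs[0].homopolymer_associated

    def test_isolated_substitution_not_homopolymer(self):
        rng = np.random.default_rng(52)
        res = _rand_seq(rng, 100) + "ACG" + _rand_seq(rng, 100)
        q = NucSequence("q", res[:101] + "T" + res[102:])  # C -> T between A and G
        ref = NucSequence("r", res)
        aln = align_assemblies(ref, q, circular=False)
        diffs = classify_differences(aln, ref, q)
        assert [d.dtype for d in diffs] == ["substitution"]
        assert not diffs[0].homopolymer_associated

    def test_insertion_in_mask_excluded_from_masked_accuracy(self):
        g, _ = make_genome(seed=46)
        res = g.residues[:500] + "G" + g.residues[500:]
        q = NucSequence("q", res, "circular")
        mask = MaskSet("r", ((480, 520),), threshold=60, mode="flanks")
        aln = align_assemblies(g, q)
        sq = synchronized_query(q, aln)
        diffs = classify_differences(aln, g, sq, mask=mask)
        ins = [d for d in diffs if d.dtype == "insertion"]
        assert len(ins) == 1 and ins[0].in_mask
        assert accuracy(diffs, len(g), exclude_masked=True) >= accuracy(diffs, len(g))
        assert accuracy(diffs, len(g), exclude_masked=True) == 100.0


class TestAccuracy:
    @pytest.mark.parametrize("d,expected", [(0, 100.0), (30, 99.80), (3, 99.98)])
    def test_stated_formula(self, d, expected):
        from mitofinish.concordance import DiffRecord

        diffs = [
            DiffRecord((i, i + 1), (i, i + 1), "substitution", 1, False, False)
            for i in range(d)
        ]
        assert accuracy(diffs, 15000) == pytest.approx(expected)

    def test_monotonic_under_added_edits(self):
        g, _ = make_genome(seed=47)
        rng = np.random.default_rng(48)
        res = list(g.residues)
        last = 100.0
        for n_edits in (5, 10, 20):
            res2 = list(res)
            for p in rng.choice(len(res2), size=n_edits, replace=False):
                res2[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[res2[p]]
            rep, _ = compare_assemblies(g, NucSequence("q", "".join(res2), "circular"))
            assert rep.accuracy_pct <= last
            last = rep.accuracy_pct


class TestErrorProfile:
    def test_empty(self):
        table = error_profile([])
        assert table.values.sum() == 0

    def test_planted_counts(self):
        g, _ = make_genome(seed=49)
        rng = np.random.default_rng(50)
        res = list(g.residues)
        # 2 substitutions in non-repeat context
        subs = 0
        p = 100
        while subs < 2:
            if len({res[p - 1], res[p], res[p + 1]}) == 3:
                res[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[res[p]]
                subs += 1
            p += 500
        # 5 single-base deletions inside homopolymer runs >= 4
        dels = []
        i = 2000
        while len(dels) < 5 and i < len(res) - 5:
            if res[i] == res[i + 1] == res[i + 2] == res[i + 3]:
                dels.append(i)
                i += 200
            else:
                i += 1
        for i in sorted(dels, reverse=True):
            del res[i]
        rep, diffs = compare_assemblies(g, NucSequence("q", "".join(res), "circular"))
        table = error_profile(diffs)
        assert table.loc["deletion", "homopolymer"] == 5
        assert table.loc["substitution", "non_homopolymer"] == 2
        assert table.values.sum() == len(diffs)
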