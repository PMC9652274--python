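"""Assembly-vs-reference concordance: alignment, diff classification,
accuracy, and the error profile.

The aligner is anchor-chained: shared 15-mers that are unique in both
sequences are chained co-linearly (after choosing the query strand and —
for circular molecules — the rotation that synchronizes the two
sequences), anchor stretches are matched by construction, and the
regions between anchors are aligned exactly by affine-gap dynamic
programming.  On sequences whose anchors lie on the optimal path this
equals a full Needleman-Wunsch/Gotoh alignment at a small fraction of
the cost; oracle tests compare the two on small inputs.

Scoring: match +1, mismatch -2, and a gap run of length L costs 4 + L
(open -4, extend -1, the first gap base paying both).

Accuracy follows the benchmarking convention
``100 * (1 - total_diff_bases / ref_len)``, with an optional variant
excluding differences inside masked (low-coverage) intervals.
Differences are counted in bases: an n-base indel contributes n.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .core import NucSequence, revcomp
from .coverage import MaskSet

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4  # charged once per gap run, on top of per-base extension
GAP_EXTEND = -1

_NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# exact affine-gap DP (Gotoh) with deterministic traceback
# ---------------------------------------------------------------------------

def gotoh_align(a: str, b: str) -> tuple[int, list[tuple[str, int]]]:
    """Optimal global alignment of two strings under the module scoring.

    Returns ``(score, ops)`` where ops is a run-length list over
    ``'='`` (match), ``'X'`` (mismatch), ``'D'`` (base of *a* deleted in
    *b*), ``'I'`` (base inserted in *b*).  Ties are broken
    diagonal-first, then deletion, then insertion, so the traceback is
    deterministic.
    """
    n, m = len(a), len(b)
    first_gap = GAP_OPEN + GAP_EXTEND
    # state matrices: M diagonal, D gap in b (vertical), I gap in a (horizontal)
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    D = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    I = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        D[i][0] = first_gap + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        I[0][j] = first_gap + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Di, Di1 = D[i], D[i - 1]
        Ii, Ii1 = I[i], I[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            Mi[j] = max(Mi1[j - 1], Di1[j - 1], Ii1[j - 1]) + s
            Di[j] = max(Mi1[j] + first_gap, Di1[j] + GAP_EXTEND, Ii1[j] + first_gap)
            Ii[j] = max(Mi[j - 1] + first_gap, Ii[j - 1] + GAP_EXTEND, Di[j - 1] + first_gap)
    # traceback; on ties prefer diagonal, then deletion, then insertion
    i, j = n, m
    vals = (M[i][j], D[i][j], I[i][j])
    state = vals.index(max(vals))
    score = int(max(vals))
    cols: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            cols.append("=" if s == MATCH else "X")
            target = M[i][j] - s
            prev = (M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            state = prev.index(target)
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append("D")
            cur = D[i][j]
            if M[i - 1][j] + first_gap == cur:
                state = 0
            elif D[i - 1][j] + GAP_EXTEND == cur:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            cols.append("I")
            cur = I[i][j]
            if M[i][j - 1] + first_gap == cur:
                state = 0
            elif D[i][j - 1] + first_gap == cur:
                state = 1
            else:
                state = 2
            j -= 1
    cols.reverse()
    return score, _run_length(cols)


def _run_length(cols: list[str]) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for c in cols:
        if ops and ops[-1][0] == c:
            ops[-1] = (c, ops[-1][1] + 1)
        else:
            ops.append((c, 1))
    return ops


# ---------------------------------------------------------------------------
# anchor machinery
# ---------------------------------------------------------------------------

ANCHOR_K = 15


def _unique_kmers(s: str, k: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for i in range(len(s) - k + 1):
        counts[s[i : i + k]] += 1
    pos = {}
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if counts[kmer] == 1 and "N" not in kmer:
            pos[kmer] = i
    return pos


def _shared_anchors(ref: str, query: str, k: int = ANCHOR_K) -> list[tuple[int, int]]:
    ru = _unique_kmers(ref, k)
    qu = _unique_kmers(query, k)
    return sorted((rp, qu[kmer]) for kmer, rp in ru.items() if kmer in qu)


def _merge_codiagonal(pairs: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge runs of consecutive co-diagonal anchor pairs into segments
    (ref_start, query_start, span) where span covers the full matched
    stretch including the trailing k-1 bases."""
    segs: list[tuple[int, int, int]] = []
    for rp, qp in pairs:
        if segs:
            rs, qs, span = segs[-1]
            if rp - rs == qp - qs and rp <= rs + span - k + 1:
                segs[-1] = (rs, qs, rp - rs + k)
                continue
        segs.append((rp, qp, k))
    return segs


def _chain_segments(segs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Heaviest strictly co-linear, non-overlapping chain (weight = span)."""
    if not segs:
        return []
    segs = sorted(segs)
    n = len(segs)
    best = [0.0] * n
    prev = [-1] * n
    for i, (rs, qs, span) in enumerate(segs):
        best[i] = span
        for j in range(i):
            rj, qj, sj = segs[j]
            if rj + sj <= rs and qj + sj <= qs and best[j] + span > best[i]:
                best[i] = best[j] + span
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(segs[end])
        end = prev[end]
    return chain[::-1]


# largest region aligned by full quadratic DP; larger regions are
# re-anchored locally (k-mers unique within the region rather than the
# whole genome) and only truly anchor-free stretches fall back to a
# unit-cost edit path
_FULL_DP_CELLS = 250_000


def _score_ops(ops: list[tuple[str, int]]) -> int:
    score = 0
    for op, n in ops:
        if op == "=":
            score += MATCH * n
        elif op == "X":
            score += MISMATCH * n
        else:
            score += GAP_OPEN + GAP_EXTEND * n
    return score


def _edlib_ops(a: str, b: str) -> list[tuple[str, int]]:
    import re

    import edlib

    res = edlib.align(b, a, mode="NW", task="path")
    ops = []
    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        ops.append((op, int(n)))
    return _run_length([op for op, n in ops for _ in range(n)])


def _align_region(a: str, b: str, depth: int = 0) -> list[tuple[str, int]]:
    """Align one inter-anchor region, re-anchoring recursively when large."""
    if not a and not b:
        return []
    if not a:
        return [("I", len(b))]
    if not b:
        return [("D", len(a))]
    if len(a) * len(b) <= _FULL_DP_CELLS:
        return gotoh_align(a, b)[1]
    if depth < 6:
        segs = _chain_segments(_merge_codiagonal(_shared_anchors(a, b), ANCHOR_K))
        if segs:
            cols: list[str] = []
            apos = bpos = 0
            for as_, bs, span in segs:
                for op, n in _align_region(a[apos:as_], b[bpos:bs], depth + 1):
                    cols.extend(op * n)
                cols.extend("=" * span)
                apos, bpos = as_ + span, bs + span
            for op, n in _align_region(a[apos:], b[bpos:], depth + 1):
                cols.extend(op * n)
            return _run_length(cols)
    return _edlib_ops(a, b)


@dataclass(frozen=True)
class Alignment:
    """End-to-end alignment of a (possibly re-rotated) query to a reference."""

    ref_id: str
    query_id: str
    ops: tuple[tuple[str, int], ...]  # run-length over =, X, I, D
    score: int
    query_strand: str  # strand of the original query used
    query_rotation: int  # rotation applied to the query before aligning
    ref_len: int
    query_len: int

    @property
    def total_diff_bases(self) -> int:
        return sum(n for op, n in self.ops if op != "=")

    @property
    def columns(self) -> int:
        return sum(n for _, n in self.ops)


class DivergentSequencesError(ValueError):
    pass


def _synchronize(ref: NucSequence, query: NucSequence, circular: bool):
    """Pick query strand and rotation maximizing shared unique anchors."""
    fwd = query.residues
    rev = revcomp(fwd)
    a_fwd = _shared_anchors(ref.residues, fwd)
    a_rev = _shared_anchors(ref.residues, rev)
    if not a_fwd and not a_rev:
        raise DivergentSequencesError(
            f"sequences too divergent: no shared unique {ANCHOR_K}-mers between "
            f"{ref.id!r} and {query.id!r}"
        )
    strand, qres, anchors = (
        ("+", fwd, a_fwd) if len(a_fwd) >= len(a_rev) else ("-", rev, a_rev)
    )
    rotation = 0
    if circular:
        rotation = _pick_rotation(anchors, len(qres))
        if rotation:
            qres = qres[rotation:] + qres[:rotation]
            anchors = _shared_anchors(ref.residues, qres)
    return strand, rotation, qres, anchors


def _pick_rotation(anchors: list[tuple[int, int]], qlen: int) -> int:
    """Rotation offset that synchronizes a circular query with the ref.

    Anchor offsets ``(qpos - rpos) mod qlen`` from the true rotation are
    smeared by interior indels, so offsets are clustered circularly and
    the dominant cluster wins; within it the offset of the anchor with
    the smallest ref position is used, so the alignment starts at the
    shared origin rather than mid-cluster.
    """
    tol = max(64, qlen // 20)
    items = sorted((qp - rp) % qlen for rp, qp in anchors)
    # circular single-linkage clustering of the sorted offsets
    clusters: list[list[int]] = [[items[0]]]
    for d in items[1:]:
        if d - clusters[-1][-1] <= tol:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    if len(clusters) > 1 and (items[0] + qlen) - clusters[-1][-1] <= tol:
        clusters[0] = clusters.pop() + clusters[0]
    dominant = max(clusters, key=len)
    member = set(dominant)
    best = min(
        (a for a in anchors if (a[1] - a[0]) % qlen in member), key=lambda a: a[0]
    )
    return (best[1] - best[0]) % qlen


def align_assemblies(
    ref: NucSequence, query: NucSequence, circular: bool = True
) -> Alignment:
    """Globally align *query* to *ref*, synchronizing strand and rotation.

    Raises :class:`DivergentSequencesError` when the two sequences share
    no unique anchor k-mers at all.
    """
    strand, rotation, qres, anchors = _synchronize(ref, query, circular)
    rres = ref.residues
    chain = _chain_segments(_merge_codiagonal(anchors, ANCHOR_K))
    cols: list[str] = []
    rpos = qpos = 0
    for rs, qs, span in chain:
        if rs > rpos or qs > qpos:
            for op, n in _align_region(rres[rpos:rs], qres[qpos:qs]):
                cols.extend(op * n)
        cols.extend("=" * span)
        rpos, qpos = rs + span, qs + span
    if rpos < len(rres) or qpos < len(qres):
        for op, n in _align_region(rres[rpos:], qres[qpos:]):
            cols.extend(op * n)
    ops = _run_length(cols)
    score = _score_ops(ops)
    return Alignment(
        ref_id=ref.id,
        query_id=query.id,
        ops=tuple(ops),
        score=score,
        query_strand=strand,
        query_rotation=rotation,
        ref_len=len(ref),
        query_len=len(query),
    )


# ---------------------------------------------------------------------------
# diff classification and the error profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffRecord:
    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    dtype: str  # insertion | deletion | substitution
    length: int
    homopolymer_associated: bool
    in_mask: bool

    def as_dict(self) -> dict:
        return {
            "ref_start": self.ref_interval[0],
            "ref_end": self.ref_interval[1],
            "query_start": self.query_interval[0],
            "query_end": self.query_interval[1],
            "dtype": self.dtype,
            "length": self.length,
            "homopolymer_associated": self.homopolymer_associated,
            "in_mask": self.in_mask,
        }


def _run_extent(s: str, pos: int, base: str) -> int:
    """Length of the maximal run of *base* in *s* touching position *pos*."""
    left = pos
    while left > 0 and s[left - 1] == base:
        left -= 1
    right = pos
    while right < len(s) and s[right] == base:
        right += 1
    return right - left


def _hp_associated(
    ref_res: str, query_res: str, dtype: str, ref_iv, query_iv, hp_run: int
) -> bool:
    if dtype == "substitution":
        rs, re_ = ref_iv
        base = ref_res[rs]
        run_start = rs
        while run_start > 0 and ref_res[run_start - 1] == base:
            run_start -= 1
        run_end = rs
        while run_end < len(ref_res) and ref_res[run_end] == base:
            run_end += 1
        return run_end - run_start >= hp_run and re_ <= run_end
    if dtype == "deletion":
        rs, re_ = ref_iv
        bases = set(ref_res[rs:re_])
        if len(bases) != 1:
            return False
        return _run_extent(ref_res, rs, bases.pop()) >= hp_run
    # insertion: inserted bases come from the query
    qs, qe = query_iv
    bases = set(query_res[qs:qe])
    if len(bases) != 1:
        return False
    return _run_extent(ref_res, ref_iv[0], bases.pop()) >= hp_run


_OP_TO_DTYPE = {"X": "substitution", "I": "insertion", "D": "deletion"}


def classify_differences(
    alignment: Alignment,
    ref: NucSequence,
    query: NucSequence,
    mask: MaskSet | None = None,
    hp_run: int = 3,
) -> list[DiffRecord]:
    """Turn alignment edit columns into classified difference events.

    Adjacent columns of the same edit type form one event.  *query* must
    be the sequence as aligned (after any strand/rotation synchronization
    recorded on the alignment); helper :func:`synchronized_query` builds
    it.  ``hp_run=3`` encodes the "any span of the same nucleotide > 2"
    homopolymer definition.
    """
    ref_res = ref.residues
    qry_res = query.residues
    records: list[DiffRecord] = []
    rpos = qpos = 0
    for op, n in alignment.ops:
        if op == "=":
            rpos += n
            qpos += n
            continue
        dtype = _OP_TO_DTYPE[op]
        if op == "X":
            ref_iv, qry_iv = (rpos, rpos + n), (qpos, qpos + n)
            rpos += n
            qpos += n
        elif op == "D":
            ref_iv, qry_iv = (rpos, rpos + n), (qpos, qpos)
            rpos += n
        else:
            ref_iv, qry_iv = (rpos, rpos), (qpos, qpos + n)
            qpos += n
        hp = _hp_associated(ref_res, qry_res, dtype, ref_iv, qry_iv, hp_run)
        if mask is None:
            in_mask = False
        elif dtype == "insertion":
            p = ref_iv[0]
            in_mask = mask.covers(max(p - 1, 0), p + 1)
        else:
            in_mask = mask.covers(*ref_iv)
        records.append(
            DiffRecord(
                ref_interval=ref_iv,
                query_interval=qry_iv,
                dtype=dtype,
                length=n,
                homopolymer_associated=hp,
                in_mask=in_mask,
            )
        )
    return records


def synchronized_query(query: NucSequence, alignment: Alignment) -> NucSequence:
    """The query as it entered the alignment (strand flip + rotation applied)."""
    res = query.residues
    if alignment.query_strand == "-":
        res = revcomp(res)
    r = alignment.query_rotation
    return query.with_residues(res[r:] + res[:r])


def accuracy(
    diffs: list[DiffRecord], ref_len: int, exclude_masked: bool = False
) -> float:
    """Sequence accuracy percent: ``100 * (1 - D / ref_len)``."""
    if ref_len <= 0:
        raise ValueError("ref_len must be positive")
    d = sum(r.length for r in diffs if not (exclude_masked and r.in_mask))
    return 100.0 * (1.0 - d / ref_len)


def error_profile(diffs: list[DiffRecord]) -> pd.DataFrame:
    """Event counts by type x homopolymer association (Fig.-3-style)."""
    table = pd.DataFrame(
        0,
        index=["insertion", "deletion", "substitution"],
        columns=["homopolymer", "non_homopolymer"],
    )
    for r in diffs:
        col = "homopolymer" if r.homopolymer_associated else "non_homopolymer"
        table.loc[r.dtype, col] += 1
    return table


@dataclass(frozen=True)
class ConcordanceReport:
    ref_len: int
    counts: dict
    total_diff_bases: int
    total_diff_bases_unmasked: int
    accuracy_pct: float
    accuracy_pct_masked: float
    homopolymer_fraction: float
    query_strand: str
    query_rotation: int

    def as_dict(self) -> dict:
        return {
            "ref_len": self.ref_len,
            "counts": dict(self.counts),
            "total_diff_bases": self.total_diff_bases,
            "total_diff_bases_unmasked": self.total_diff_bases_unmasked,
            "accuracy_pct": round(self.accuracy_pct, 4),
            "accuracy_pct_masked": round(self.accuracy_pct_masked, 4),
            "homopolymer_fraction": round(self.homopolymer_fraction, 4),
            "query_strand": self.query_strand,
            "query_rotation": self.query_rotation,
        }


def compare_assemblies(
    ref: NucSequence,
    query: NucSequence,
    mask: MaskSet | None = None,
    circular: bool = True,
    hp_run: int = 3,
) -> tuple[ConcordanceReport, list[DiffRecord]]:
    """Full concordance analysis of one query assembly against a reference."""
    aln = align_assemblies(ref, query, circular=circular)
    sync_q = synchronized_query(query, aln)
    diffs = classify_differences(aln, ref, sync_q, mask=mask, hp_run=hp_run)
    d_all = sum(r.length for r in diffs)
    d_unmasked = sum(r.length for r in diffs if not r.in_mask)
    d_hp = sum(r.length for r in diffs if r.homopolymer_associated)
    counts = Counter(r.dtype for r in diffs)
    report = ConcordanceReport(
        ref_len=len(ref),
        counts={k: counts.get(k, 0) for k in ("insertion", "deletion", "substitution")},
        total_diff_bases=d_all,
        total_diff_bases_unmasked=d_unmasked,
        accuracy_pct=accuracy(diffs, len(ref)),
        accuracy_pct_masked=accuracy(diffs, len(ref), exclude_masked=True),
        homopolymer_fraction=(d_hp / d_all) if d_all else 0.0,
        query_strand=aln.query_strand,
        query_rotation=aln.query_rotation,
    )
    return report, diffs
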