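"""Deterministic synthetic mitogenome generator with a truth log.

Emulates the raw material the finishing pipeline sees: an A/T-rich
~15 kb circular genome with a full mitochondrial gene complement
(13 CDS / 22 tRNA / 2 rRNA plus control region(s)), an
assembler-style linear contig carrying a duplicated terminal overlap,
planted single-base deletions in long A/T homopolymer runs inside CDSs
(the characteristic nanopore error), and a per-base depth track with
optional low-coverage intervals.  Every output is a pure function of the
seed, and the truth bundle records exactly what was planted so tests can
verify recovery.

Background CDS codons exclude the stop codons and the two
single-codon homopolymer builders (AAA, TTT), which caps background A/T
runs inside a CDS at 4 bases; long runs are then planted explicitly as
AAA/TTT codon blocks, so each planted run is the unique run >= 8 of its
gene and the expected correction is unambiguous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .core import CIRCULAR, LINEAR, DepthTrack, Feature, NucSequence, revcomp
from .framefix import EditRecord, find_premature_stops

# typical invertebrate-mitochondrial gene complement (lengths in nt,
# CDS lengths divisible by 3)
_CDS_TEMPLATE = [
    ("cox1", 1536), ("cox2", 684), ("atp8", 159), ("atp6", 672),
    ("cox3", 786), ("nad3", 351), ("nad5", 1650), ("nad4", 1338),
    ("nad4l", 294), ("nad6", 498), ("cob", 1128), ("nad1", 936),
    ("nad2", 960),
]
_MINUS_CDS = {"nad5", "nad4", "nad4l", "nad1"}
_TRNA_NAMES = [
    "trnM", "trnW", "trnC", "trnY", "trnL1", "trnL2", "trnK", "trnD",
    "trnG", "trnA", "trnR", "trnN", "trnS1", "trnS2", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnI", "trnQ", "trnV",
]
_MINUS_TRNA = {"trnC", "trnY", "trnQ", "trnV"}
_TRNA_LEN = 64
_RRNA_TEMPLATE = [("rrnL", 1200), ("rrnS", 750)]

_STOPS = {"TAA", "TAG"}  # translation table 5
_EXCLUDED_CODONS = _STOPS | {"AAA", "TTT"}
_ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


def _codon_pool(at_fraction: float) -> tuple[list[str], np.ndarray]:
    pa = at_fraction / 2
    pc = (1 - at_fraction) / 2
    base_p = {"A": pa, "T": pa, "C": pc, "G": pc}
    pool = [c for c in _ALL_CODONS if c not in _EXCLUDED_CODONS]
    w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in pool])
    return pool, w / w.sum()


def _random_bases(rng: np.random.Generator, n: int, at_fraction: float) -> str:
    pa = at_fraction / 2
    pc = (1 - at_fraction) / 2
    return "".join(rng.choice(list("ATCG"), size=n, p=[pa, pa, pc, pc]))


def _make_cds(rng: np.random.Generator, length: int, at_fraction: float) -> str:
    """A valid table-5 ORF: ATG start, stop-free body, TAA stop, with one
    planted AAA/TTT homopolymer block (run of 9 or 12)."""
    if length % 3 or length < 30:
        raise ValueError(f"CDS length {length} must be a multiple of 3 and >= 30")
    pool, w = _codon_pool(at_fraction)
    n_body = length // 3 - 2
    idx = rng.choice(len(pool), size=n_body, p=w)
    body = [pool[i] for i in idx]
    # plant the gene's unique long homopolymer run
    m = int(rng.integers(3, 5))  # 3 or 4 codons -> run of 9 or 12
    base = "A" if rng.random() < 0.5 else "T"
    pos = int(rng.integers(2, n_body - m - 2))
    body[pos : pos + m] = [base * 3] * m
    return "ATG" + "".join(body) + "TAA"


def make_genome(
    seed: int,
    length: int = 15000,
    organization: str = "groupB",
    n_cds: int = 13,
    n_trna: int = 22,
    n_rrna: int = 2,
    at_fraction: float = 0.75,
) -> tuple[NucSequence, list[Feature]]:
    """Build one circular genome with its feature annotation.

    ``organization`` selects the simplified gene-organization template:
    groupA carries two control regions, groupB one.  The methionine tRNA
    is placed first, at position 0 on the plus strand, matching the
    publication convention the orientation module restores.
    """
    if organization not in ("groupA", "groupB"):
        raise ValueError(f"unknown organization {organization!r}")
    rng = np.random.default_rng(seed)
    seq_id = f"synthetic_mito_seed{seed}"
    cds_list = list(_CDS_TEMPLATE[:n_cds]) + [
        (f"orf{i}", 300) for i in range(max(0, n_cds - len(_CDS_TEMPLATE)))
    ]
    trna_list = list(_TRNA_NAMES[:n_trna])
    rrna_list = list(_RRNA_TEMPLATE[:n_rrna])

    # gene order: trnM first, then CDSs with tRNAs interleaved, rRNAs,
    # control region(s) at the end
    plan: list[tuple[str, str, int, str]] = []  # (name, ftype, length, strand)
    plan.append(("trnM", "tRNA", _TRNA_LEN, "+"))
    rest_trna = [t for t in trna_list if t != "trnM"]
    for i, (name, ln) in enumerate(cds_list):
        plan.append((name, "CDS", ln, "-" if name in _MINUS_CDS else "+"))
        if i < len(rest_trna):
            t = rest_trna[i]
            plan.append((t, "tRNA", _TRNA_LEN, "-" if t in _MINUS_TRNA else "+"))
    for t in rest_trna[len(cds_list):]:
        plan.append((t, "tRNA", _TRNA_LEN, "-" if t in _MINUS_TRNA else "+"))
    for name, ln in rrna_list:
        plan.append((name, "rRNA", ln, "-"))

    n_cr = 2 if organization == "groupA" else 1
    fixed = sum(p[2] for p in plan)
    spare = length - fixed
    if spare < 60 * n_cr:
        raise ValueError(
            f"infeasible geometry: {fixed} nt of genes leave {spare} nt for "
            f"{n_cr} control region(s) in a {length} nt genome"
        )
    cr_lens = [spare // n_cr] * n_cr
    cr_lens[-1] += spare - sum(cr_lens)
    for i, ln in enumerate(cr_lens):
        plan.append((f"CR{i + 1}" if n_cr > 1 else "CR", "control_region", ln, "+"))

    segments: list[str] = []
    features: list[Feature] = []
    pos = 0
    for name, ftype, ln, strand in plan:
        if ftype == "CDS":
            gene = _make_cds(rng, ln, at_fraction)
            seg = revcomp(gene) if strand == "-" else gene
        else:
            seg = _random_bases(rng, ln, at_fraction)
        segments.append(seg)
        features.append(
            Feature(
                seq_id=seq_id, name=name, ftype=ftype,
                start=pos, end=pos + ln, strand=strand,
            )
        )
        pos += ln
    genome = NucSequence(id=seq_id, residues="".join(segments), topology=CIRCULAR)
    assert len(genome) == length
    return genome, features


def linearize_with_overlap(
    genome: NucSequence,
    rotation: int,
    overlap_len: int,
    seed: int = 0,
    overlap_error_rate: float = 0.0,
) -> NucSequence:
    """Assembler-style linear contig: rotated genome plus duplicated start."""
    if overlap_len >= len(genome):
        raise ValueError("overlap must be shorter than the genome")
    rot = genome.rotated(rotation % len(genome))
    overlap = list(rot.residues[:overlap_len])
    if overlap_error_rate > 0:
        rng = np.random.default_rng(seed)
        for i in range(overlap_len):
            if rng.random() < overlap_error_rate:
                overlap[i] = rng.choice([b for b in "ACGT" if b != overlap[i]])
    return NucSequence(
        id=genome.id + "_contig",
        residues=rot.residues + "".join(overlap),
        topology=LINEAR,
    )


def _shift_after_deletion(features: list[Feature], pos: int) -> list[Feature]:
    out = []
    for f in features:
        out.append(
            replace(
                f,
                start=f.start - 1 if f.start > pos else f.start,
                end=f.end - 1 if f.end > pos else f.end,
            )
        )
    return out


def eligible_deletion_sites(
    seq: NucSequence,
    features: list[Feature],
    min_run: int = 8,
    unique_only: bool = True,
) -> list[tuple[Feature, int, int, str]]:
    """CDS homopolymer runs a deletion may be planted in.

    Returns ``(cds, run_start_gene, run_len, base)`` per gene; with
    ``unique_only`` a gene qualifies only when it has exactly one A/T run
    >= min_run, so the downstream correction target is unambiguous.
    """
    sites = []
    for f in features:
        if f.ftype != "CDS":
            continue
        gene = f.extract(seq)
        runs = []
        i = 0
        while i < len(gene):
            j = i + 1
            while j < len(gene) and gene[j] == gene[i]:
                j += 1
            if gene[i] in "AT" and j - i >= min_run:
                runs.append((i, j - i, gene[i]))
            i = j
        if not runs:
            continue
        if unique_only and len(runs) != 1:
            continue
        run_start, run_len, base = runs[0]
        # deletions at the gene's very ends cannot shift enough frame to
        # produce a detectable premature stop
        if run_start + run_len < len(gene) - 30:
            sites.append((f, run_start, run_len, base))
    return sites


def inject_homopolymer_deletions(
    seq: NucSequence,
    features: list[Feature],
    n: int,
    min_run: int = 8,
    seed: int = 0,
    unique_only: bool = True,
) -> tuple[NucSequence, list[EditRecord], list[Feature]]:
    """Delete one base from *n* distinct CDS homopolymer runs.

    Only deletions that actually cause a premature stop are planted (the
    error class the frame fixer exists for).  Returns the mutated
    sequence, the truth edits (genome coordinates on the plus strand of
    the *original* sequence), and the feature list shifted to match the
    mutated sequence.
    """
    rng = np.random.default_rng(seed)
    sites = eligible_deletion_sites(seq, features, min_run, unique_only)
    # keep only sites whose deletion provably frameshifts into a stop
    verified = []
    for f, run_start, run_len, base in sites:
        gpos = _genome_pos_of_run_end(f, run_start, run_len, len(seq))
        trial = seq.with_residues(seq.residues[:gpos] + seq.residues[gpos + 1 :])
        trial_cds = _shift_after_deletion([f], gpos)[0]
        if find_premature_stops(trial, trial_cds):
            verified.append((f, run_start, run_len, base))
    if len(verified) < n:
        raise ValueError(
            f"only {len(verified)} eligible homopolymer runs for {n} deletions"
        )
    order = rng.permutation(len(verified))[:n]
    chosen = sorted(
        (verified[i] for i in order),
        key=lambda s: _genome_pos_of_run_end(s[0], s[1], s[2], len(seq)),
        reverse=True,
    )
    cur_seq, cur_feats = seq, list(features)
    edits: list[EditRecord] = []
    for f, run_start, run_len, base in chosen:
        gpos = _genome_pos_of_run_end(f, run_start, run_len, len(seq))
        genome_base = cur_seq.residues[gpos]
        cur_seq = cur_seq.with_residues(
            cur_seq.residues[:gpos] + cur_seq.residues[gpos + 1 :]
        )
        cur_feats = _shift_after_deletion(cur_feats, gpos)
        edits.append(
            EditRecord(
                seq_id=seq.id, position=gpos, op="delete", base=genome_base,
                gene=f.name, run_len_before=run_len,
            )
        )
    return cur_seq, list(reversed(edits)), cur_feats


def _genome_pos_of_run_end(
    cds: Feature, run_start: int, run_len: int, seq_len: int
) -> int:
    """Genome position of the run's last base (gene orientation 3' end)."""
    gene_pos = run_start + run_len - 1
    if cds.strand == "+":
        return cds.start + gene_pos
    return cds.end - 1 - gene_pos


def simulate_depth(
    length: int,
    baseline: int = 300,
    low_intervals: tuple[tuple[int, int], ...] = (),
    low_value: int = 20,
    seed: int = 0,
    jitter: float = 0.1,
    seq_id: str = "synthetic",
) -> DepthTrack:
    """Baseline depth with multiplicative jitter and low-coverage windows."""
    rng = np.random.default_rng(seed)
    if jitter > 0:
        vals = np.rint(baseline * rng.uniform(1 - jitter, 1 + jitter, size=length))
    else:
        vals = np.full(length, baseline, dtype=float)
    for s, e in low_intervals:
        if not (0 <= s < e <= length):
            raise ValueError(f"low interval [{s},{e}) outside [0,{length})")
        vals[s:e] = low_value
    return DepthTrack(seq_id=seq_id, depth=tuple(int(v) for v in vals))


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything the simulator planted, for round-trip verification."""

    seed: int
    genome: NucSequence
    features: list[Feature]
    rotation: int
    overlap_len: int
    planted_edits: list[EditRecord]
    low_cov_intervals: tuple[tuple[int, int], ...]
    at_fraction: float
    genome_with_errors: NucSequence = None
    features_with_errors: list[Feature] = None
    features_contig: list[Feature] = None  # same features in the contig frame
    contig: NucSequence = None
    depth: DepthTrack = None
    anchor: NucSequence = None

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genome_id": self.genome.id,
            "genome_len": len(self.genome),
            "rotation": self.rotation,
            "overlap_len": self.overlap_len,
            "at_fraction": self.at_fraction,
            "planted_edits": [
                {
                    "position": e.position, "op": e.op, "base": e.base,
                    "gene": e.gene, "run_len_before": e.run_len_before,
                }
                for e in self.planted_edits
            ],
            "low_cov_intervals": [list(iv) for iv in self.low_cov_intervals],
        }


def simulate_bundle(
    seed: int,
    length: int = 15000,
    organization: str = "groupB",
    n_deletions: int = 3,
    overlap_len: int | None = None,
    rotation: int | None = None,
    at_fraction: float = 0.75,
    baseline_depth: int = 300,
    low_intervals: tuple[tuple[int, int], ...] = (),
) -> SyntheticTruth:
    """One complete test substrate: truth genome, erroneous contig, depth."""
    rng = np.random.default_rng(seed)
    genome, features = make_genome(
        seed, length=length, organization=organization, at_fraction=at_fraction
    )
    if rotation is None:
        rotation = int(rng.integers(0, length))
    if overlap_len is None:
        overlap_len = int(rng.integers(50, 501))
    if n_deletions:
        mut_seq, edits, mut_feats = inject_homopolymer_deletions(
            genome, features, n=n_deletions, seed=seed + 1
        )
    else:
        mut_seq, edits, mut_feats = genome, [], list(features)
    contig = linearize_with_overlap(mut_seq, rotation, overlap_len, seed=seed + 2)
    # the same annotation expressed in the rotated (contig/circularized) frame
    from .orient import rotate_feature

    feats_contig = [rotate_feature(f, rotation, len(mut_seq)) for f in mut_feats]
    depth = simulate_depth(
        len(mut_seq),
        baseline=baseline_depth,
        low_intervals=low_intervals,
        seed=seed + 3,
        seq_id=mut_seq.id,
    )
    trn_m = next(f for f in features if f.name == "trnM")
    anchor = NucSequence(id="trnM_anchor", residues=trn_m.extract(genome))
    return SyntheticTruth(
        seed=seed,
        genome=genome,
        features=features,
        rotation=rotation,
        overlap_len=overlap_len,
        planted_edits=edits,
        low_cov_intervals=tuple(low_intervals),
        at_fraction=at_fraction,
        genome_with_errors=mut_seq,
        features_with_errors=mut_feats,
        features_contig=feats_contig,
        contig=contig,
        depth=depth,
        anchor=anchor,
    )
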