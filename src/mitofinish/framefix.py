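"""Homopolymer frameshift correction in protein-coding genes.

Nanopore assemblies of A/T-rich mitogenomes carry characteristic
single-base deletions in long homopolymer runs; inside a CDS these shift
the reading frame and surface as premature stop codons.  The repair rule
implemented here: find the first premature stop of each CDS, walk the
candidate A/T homopolymer runs upstream of it (nearest to the stop
first), and insert one copy of the run's base at the run's 3' end; keep
the first insertion that removes the stop without creating an earlier
one.  Runs of length >= ``min_run`` (default 8, matching the length class
where these errors concentrate) are tried first; if none works the
search falls back to the general homopolymer definition (any run of more
than 2 identical bases, ``fallback_min_run=3``).

Only single-base insertions into CDS intervals are automated; larger
deletions need supporting read alignments and are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Data import CodonTable

from .core import Feature, NucSequence, homopolymer_runs, revcomp, translate


@dataclass(frozen=True)
class EditRecord:
    """One accepted single-base insertion."""

    seq_id: str
    position: int  # 0-based genome coordinate the base is inserted before
    op: str
    base: str
    gene: str
    run_len_before: int
    reason: str = "homopolymer-frameshift"


@dataclass
class FrameReport:
    gene: str
    premature_stops_before: int
    edits: list[EditRecord] = field(default_factory=list)
    resolved: bool = False


def _stop_codons(table: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[table].stop_codons)


def find_premature_stops(seq: NucSequence, cds: Feature) -> list[int]:
    """Codon indices of in-frame stops strictly before the final codon.

    The final codon is exempt even when truncated (mitochondrial CDSs
    commonly end in an incomplete T/TA stop completed by polyadenylation).
    """
    if cds.ftype != "CDS":
        raise ValueError(f"{cds.name!r} is not a CDS")
    gene_seq = cds.extract(seq)
    if len(gene_seq) < 6:
        raise ValueError(f"CDS {cds.name!r} shorter than 6 nt")
    stops = _stop_codons(cds.transl_table)
    n_codons = len(gene_seq) // 3  # trailing partial codon never counted
    last_full = n_codons - 1 if len(gene_seq) % 3 == 0 else n_codons
    out = []
    for ci in range(min(n_codons, last_full)):
        if gene_seq[3 * ci : 3 * ci + 3] in stops:
            out.append(ci)
    return out


def find_candidate_homopolymers(
    seq: NucSequence,
    cds: Feature,
    stop_codon_index: int,
    min_run: int = 8,
    bases: frozenset[str] = frozenset("AT"),
) -> list[tuple[int, int, str]]:
    """A/T runs upstream of the premature stop, nearest-to-stop first.

    Returns ``(run_start, run_len, base)`` tuples in gene coordinates
    (0 = first base of the CDS in gene orientation), restricted to the
    interval ``[0, 3 * stop_codon_index)``.
    """
    gene_seq = cds.extract(seq)
    limit = 3 * stop_codon_index
    runs = []
    for start, end, base in homopolymer_runs(gene_seq[:limit]):
        if base in bases and end - start >= min_run:
            runs.append((start, end - start, base))
    runs.sort(key=lambda r: r[0] + r[1], reverse=True)  # 3' end closest to stop first
    return runs


def _gene_to_genome_insertion(cds: Feature, gene_pos: int, seq_len: int) -> int:
    """Genome coordinate that inserting before gene position *gene_pos* maps to."""
    if cds.strand == "+":
        return (cds.start + gene_pos) % seq_len if cds.wrap else cds.start + gene_pos
    # minus strand: gene index i sits at genome index (end - 1 - i)
    if cds.wrap:
        return (cds.end - gene_pos) % seq_len
    return cds.end - gene_pos


def shift_features(
    features: list[Feature], insertion_position: int, offset: int = 1
) -> list[Feature]:
    """Shift feature coordinates after inserting *offset* bases.

    A boundary at or after the insertion point moves by *offset*; a
    feature spanning the point therefore grows.  Wrapped features are
    handled per boundary.
    """
    out = []
    for f in features:
        new_start = f.start + offset if f.start >= insertion_position else f.start
        new_end = f.end + offset if f.end > insertion_position else f.end
        out.append(replace(f, start=new_start, end=new_end))
    return out


def _insert_base(residues: str, pos: int, base: str) -> str:
    return residues[:pos] + base + residues[pos:]


def correct_frameshifts(
    seq: NucSequence,
    features: list[Feature],
    min_run: int = 8,
    fallback_min_run: int = 3,
    max_edits_per_gene: int = 3,
) -> tuple[NucSequence, list[Feature], list[FrameReport]]:
    """Repair premature stops in every CDS by homopolymer insertion.

    Returns the corrected sequence, coordinate-shifted features, and one
    :class:`FrameReport` per CDS.  Genes that cannot be repaired are
    reported with ``resolved=False``; nothing is dropped silently.
    """
    if not any(f.ftype == "CDS" for f in features):
        raise ValueError("no CDS features to check")
    cur_seq = seq
    cur_feats = list(features)
    reports: list[FrameReport] = []
    for idx in range(len(cur_feats)):
        cds = cur_feats[idx]
        if cds.ftype != "CDS":
            continue
        stops0 = find_premature_stops(cur_seq, cds)
        report = FrameReport(gene=cds.name, premature_stops_before=len(stops0))
        if not stops0:
            report.resolved = True
            reports.append(report)
            continue
        for _ in range(max_edits_per_gene):
            cds = cur_feats[idx]
            stops = find_premature_stops(cur_seq, cds)
            if not stops:
                break
            first_stop = stops[0]
            accepted = None
            for run_threshold in (min_run, fallback_min_run):
                candidates = find_candidate_homopolymers(
                    cur_seq, cds, first_stop, min_run=run_threshold
                )
                if run_threshold == fallback_min_run:
                    # drop runs already tried in the first tier
                    candidates = [c for c in candidates if c[1] < min_run]
                for run_start, run_len, base in candidates:
                    gene_pos = run_start + run_len  # 3' end of the run
                    genome_pos = _gene_to_genome_insertion(
                        cds, gene_pos, len(cur_seq)
                    )
                    ins_base = base if cds.strand == "+" else revcomp(base)
                    trial_res = _insert_base(cur_seq.residues, genome_pos, ins_base)
                    trial_seq = cur_seq.with_residues(trial_res)
                    trial_feats = shift_features(cur_feats, genome_pos, 1)
                    trial_stops = find_premature_stops(trial_seq, trial_feats[idx])
                    if not trial_stops or trial_stops[0] > first_stop:
                        accepted = EditRecord(
                            seq_id=cur_seq.id,
                            position=genome_pos,
                            op="insert",
                            base=ins_base,
                            gene=cds.name,
                            run_len_before=run_len,
                        )
                        cur_seq, cur_feats = trial_seq, trial_feats
                        break
                if accepted:
                    break
            if accepted is None:
                break  # nothing upstream fixes this stop
            report.edits.append(accepted)
        report.resolved = not find_premature_stops(cur_seq, cur_feats[idx])
        reports.append(report)
    return cur_seq, cur_feats, reports
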