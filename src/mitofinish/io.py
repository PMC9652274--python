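"""Readers and writers for FASTA, FASTQ, GFF3 / feature-TSV, depth TSV.

GFF3 intervals (1-based closed) are converted to the internal 0-based
half-open convention on read and back on write.  Origin-wrapping features
cannot be expressed as a single GFF3 interval, so the GFF3 writer splits
them into two records sharing an ID; the lossless container for wrapped
features is the internal TSV dialect (start > end form).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO

from .core import (
    CIRCULAR,
    FEATURE_TYPES,
    LINEAR,
    DepthTrack,
    Feature,
    NucSequence,
    Read,
    logger,
    normalize_residues,
)

_TSV_HEADER = ["seq_id", "name", "ftype", "start", "end", "strand", "transl_table", "wrap"]


def read_fasta(path: str | os.PathLike) -> list[NucSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    seqs: list[NucSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            residues, n_demoted = normalize_residues(raw)
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from exc
        if n_demoted:
            logger.warning(
                "%s: %d ambiguity symbol(s) in %r demoted to N", path, n_demoted, rec.id
            )
        seqs.append(NucSequence(id=rec.id, residues=residues, topology=LINEAR))
    return seqs


def write_fasta(
    seqs: Sequence[NucSequence], path: str | os.PathLike, line_width: int = 70
) -> str:
    if not seqs:
        raise ValueError("refusing to write an empty FASTA")
    with open(path, "w", newline="\n") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), line_width):
                fh.write(s.residues[i : i + line_width] + "\n")
    return str(path)


def read_fastq(path: str | os.PathLike) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        reads.append(Read(id=rec.id, residues=str(rec.seq).upper(), qualities=quals))
    if not reads:
        raise ValueError(f"{path}: no FASTQ records")
    return reads


def write_fastq(reads: Sequence[Read], path: str | os.PathLike) -> str:
    with open(path, "w", newline="\n") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.residues}\n+\n{qual}\n")
    return str(path)


def _gff3_attrs(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


# GFF3 type column spellings accepted for each internal feature type.
_GFF3_TYPE_MAP = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "control_region": "control_region",
    "D_loop": "control_region",
    "region": "control_region",
}


def read_features(path: str | os.PathLike, dialect: str | None = None) -> list[Feature]:
    """Parse GFF3 (1-based closed) or internal TSV (0-based half-open).

    ``dialect`` is ``"gff3"`` or ``"tsv"``; inferred from the extension
    when omitted.
    """
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".txt")) else "gff3"
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "tsv":
        return _read_feature_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gff3(path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seq_id, _src, ftype_raw, start1, end1, _score, strand, _phase, attrs_raw = cols
            if ftype_raw not in _GFF3_TYPE_MAP:
                raise ValueError(
                    f"{path}:{lineno}: unknown feature type {ftype_raw!r} in line: {line}"
                )
            start1, end1 = int(start1), int(end1)
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end {end1} < start {start1}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            attrs = _gff3_attrs(attrs_raw)
            name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or ftype_raw
            table = int(attrs.get("transl_table", 5))
            feats.append(
                Feature(
                    seq_id=seq_id,
                    name=name,
                    ftype=_GFF3_TYPE_MAP[ftype_raw],
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    transl_table=table,
                )
            )
    return feats


def _read_feature_tsv(path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_HEADER)] != _TSV_HEADER[: len(header)]:
            raise ValueError(f"{path}: bad TSV header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            row = dict(zip(_TSV_HEADER, cols))
            wrap = row.get("wrap", "false").lower() == "true"
            start, end = int(row["start"]), int(row["end"])
            if not wrap and end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            feats.append(
                Feature(
                    seq_id=row["seq_id"],
                    name=row["name"],
                    ftype=row["ftype"],
                    start=start,
                    end=end,
                    strand=row["strand"],
                    transl_table=int(row.get("transl_table") or 5),
                    wrap=wrap,
                )
            )
    return feats


def write_features(
    features: Sequence[Feature],
    path: str | os.PathLike,
    dialect: str | None = None,
    seq_lengths: dict[str, int] | None = None,
) -> str:
    """Write features as GFF3 or internal TSV.

    ``seq_lengths`` is required by the GFF3 dialect when any feature
    wraps the origin (the wrapped interval is split at the origin).
    """
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".txt")) else "gff3"
    with open(path, "w", newline="\n") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for f in features:
                attrs = f"ID={f.name};Name={f.name};transl_table={f.transl_table}"
                if f.wrap:
                    if not seq_lengths or f.seq_id not in seq_lengths:
                        raise ValueError(
                            f"GFF3 export of wrapped feature {f.name!r} needs seq_lengths"
                        )
                    seq_len = seq_lengths[f.seq_id]
                    # split the origin-spanning interval into two records
                    fh.write(
                        f"{f.seq_id}\tmitofinish\t{f.ftype}\t{f.start + 1}\t"
                        f"{seq_len}\t.\t{f.strand}\t.\t{attrs};part=1\n"
                    )
                    fh.write(
                        f"{f.seq_id}\tmitofinish\t{f.ftype}\t1\t{f.end}\t.\t"
                        f"{f.strand}\t.\t{attrs};part=2\n"
                    )
                else:
                    fh.write(
                        f"{f.seq_id}\tmitofinish\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                        f"{f.strand}\t.\t{attrs}\n"
                    )
        elif dialect == "tsv":
            fh.write("\t".join(_TSV_HEADER) + "\n")
            for f in features:
                fh.write(
                    f"{f.seq_id}\t{f.name}\t{f.ftype}\t{f.start}\t{f.end}\t"
                    f"{f.strand}\t{f.transl_table}\t{str(f.wrap).lower()}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return str(path)


def read_depth(path: str | os.PathLike, length: int | None = None) -> DepthTrack:
    """Expand a depth TSV to a dense per-position array.

    Accepts bedGraph-like runs ``(seq_id, start, end, depth)`` (half-open)
    or per-base rows ``(seq_id, pos, depth)``.  Positions not covered by
    any row get depth 0.
    """
    rows = []
    seq_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.split()
            if len(cols) == 4:
                sid, start, end, depth = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
            elif len(cols) == 3:
                sid, pos, depth = cols[0], int(cols[1]), int(cols[2])
                start, end = pos, pos + 1
            else:
                raise ValueError(f"{path}:{lineno}: expected 3 or 4 columns")
            if seq_id is None:
                seq_id = sid
            elif sid != seq_id:
                raise ValueError(f"{path}:{lineno}: multiple sequence ids in one track")
            if end <= start or depth < 0:
                raise ValueError(f"{path}:{lineno}: bad interval or negative depth")
            rows.append((start, end, depth))
    if seq_id is None:
        raise ValueError(f"{path}: no depth rows")
    n = length if length is not None else max(e for _, e, _ in rows)
    dense = [0] * n
    assigned = [False] * n
    for start, end, depth in rows:
        if end > n:
            raise ValueError(
                f"{path}: run [{start},{end}) exceeds sequence length {n}"
            )
        for i in range(start, end):
            if assigned[i] and dense[i] != depth:
                raise ValueError(
                    f"{path}: conflicting depth at position {i} ({dense[i]} vs {depth})"
                )
            dense[i] = depth
            assigned[i] = True
    return DepthTrack(seq_id=seq_id, depth=tuple(dense))


def write_depth(track: DepthTrack, path: str | os.PathLike) -> str:
    """Write as bedGraph-like runs (adjacent equal depths merged)."""
    with open(path, "w", newline="\n") as fh:
        i, n = 0, len(track.depth)
        while i < n:
            j = i + 1
            while j < n and track.depth[j] == track.depth[i]:
                j += 1
            fh.write(f"{track.seq_id}\t{i}\t{j}\t{track.depth[i]}\n")
            i = j
    return str(path)


def write_mask_bed(seq_id: str, intervals: Iterable[tuple[int, int]], path) -> str:
    with open(path, "w", newline="\n") as fh:
        for start, end in intervals:
            fh.write(f"{seq_id}\t{start}\t{end}\n")
    return str(path)


def read_mask_bed(path) -> list[tuple[int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                cols = line.split()
                out.append((int(cols[1]), int(cols[2])))
    return out
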