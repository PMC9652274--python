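"""Anchor-based reorientation of circular assemblies.

Mitogenome assemblies are conventionally published starting at the
methionine tRNA on the plus strand.  The anchor (a close relative's trnM,
or any short gene) is located by edit-distance search over the doubled
sequence — so occurrences crossing the origin are found — on both
strands, and the assembly is reverse-complemented and/or rotated so the
anchor begins at position 0 in plus sense.  Feature annotations are
re-mapped through the same transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import edlib

from .core import Feature, NucSequence, revcomp


@dataclass(frozen=True)
class AnchorHit:
    position: int  # 0-based start on the plus strand of the stored sequence
    strand: str  # strand the anchor reads 5'->3' on
    mismatches: int  # edit distance of the best occurrence
    anchor_len: int


class AnchorNotFoundError(ValueError):
    pass


class AmbiguousAnchorError(ValueError):
    pass


def locate_anchor(
    circ: NucSequence, anchor: NucSequence, max_mismatch_frac: float = 0.25
) -> AnchorHit:
    """Best occurrence of *anchor* in the circular sequence, either strand.

    Raises :class:`AnchorNotFoundError` if nothing scores within
    ``ceil(max_mismatch_frac * |anchor|)`` edits, and
    :class:`AmbiguousAnchorError` when two distinct sites tie.
    """
    if not circ.circular:
        raise ValueError(f"{circ.id!r} must be circular for anchoring")
    alen = len(anchor)
    if not 20 <= alen <= 120:
        raise ValueError(f"anchor length {alen} outside the supported 20-120 nt")
    L = len(circ)
    doubled = circ.residues + circ.residues
    k = math.ceil(max_mismatch_frac * alen)

    hits: list[tuple[int, int, str]] = []  # (distance, position mod L, strand)
    for strand, query in (("+", anchor.residues), ("-", revcomp(anchor.residues))):
        res = edlib.align(query, doubled, mode="HW", task="locations", k=k)
        if res["editDistance"] < 0:
            continue
        for start, _end in res["locations"]:
            hits.append((res["editDistance"], start % L, strand))
    if not hits:
        raise AnchorNotFoundError(
            f"anchor {anchor.id!r} not found in {circ.id!r} within {k} edits"
        )
    best_dist = min(h[0] for h in hits)
    best = sorted({(p, s) for d, p, s in hits if d == best_dist})
    # collapse reports that describe the same site (e.g. equal-cost
    # alignments whose starts differ by an indel)
    sites: list[tuple[int, str]] = []
    for pos, strand in best:
        if not any(
            s == strand and min((pos - p) % L, (p - pos) % L) < alen for p, s in sites
        ):
            sites.append((pos, strand))
    if len(sites) > 1:
        raise AmbiguousAnchorError(
            f"anchor {anchor.id!r} matches {circ.id!r} equally well at "
            f"{len(sites)} distinct sites: {sites}"
        )
    pos, strand = sites[0]
    return AnchorHit(position=pos, strand=strand, mismatches=best_dist, anchor_len=alen)


def rotate_feature(f: Feature, rot: int, seq_len: int) -> Feature:
    """Re-map one feature after rotating the circle so *rot* becomes 0."""
    length = f.length(seq_len)
    new_start = (f.start - rot) % seq_len
    new_end = new_start + length
    if new_end <= seq_len:
        return replace(f, start=new_start, end=new_end, wrap=False)
    return replace(f, start=new_start, end=new_end - seq_len, wrap=True)


def revcomp_feature(f: Feature, seq_len: int) -> Feature:
    """Re-map one feature after reverse-complementing the circle."""
    flipped = "-" if f.strand == "+" else "+"
    if not f.wrap:
        return replace(
            f, start=(seq_len - f.end) % seq_len if f.end == seq_len else seq_len - f.end,
            end=seq_len - f.start, strand=flipped, wrap=False,
        )
    return replace(
        f, start=seq_len - f.end, end=seq_len - f.start, strand=flipped, wrap=True
    )


def rotate_to_anchor(
    circ: NucSequence, hit: AnchorHit, features: list[Feature] | None = None
) -> tuple[NucSequence, list[Feature]]:
    """Rotate (and flip if needed) so the anchor starts at 0 in plus sense."""
    features = list(features or [])
    L = len(circ)
    seq = circ
    if hit.strand == "-":
        seq = seq.reverse_complement()
        features = [revcomp_feature(f, L) for f in features]
        rot = (L - (hit.position + hit.anchor_len)) % L
    else:
        rot = hit.position
    out_seq = seq.rotated(rot)
    out_feats = [rotate_feature(f, rot, L) for f in features]
    return out_seq, out_feats


def orient(
    circ: NucSequence,
    anchor: NucSequence,
    features: list[Feature] | None = None,
    max_mismatch_frac: float = 0.25,
) -> tuple[NucSequence, list[Feature], AnchorHit]:
    hit = locate_anchor(circ, anchor, max_mismatch_frac)
    out_seq, out_feats = rotate_to_anchor(circ, hit, features)
    return out_seq, out_feats, hit
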