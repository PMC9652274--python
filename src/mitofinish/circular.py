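"""Circularization: terminal-overlap detection, trimming, length QC.

An assembler walking past the origin of a circular molecule emits a
linear contig whose 3' end repeats its 5' start.  Detection here is
seed-and-extend: the exact ``seed_len``-mer prefix of the contig is
searched for in the terminal ``max_overlap`` window; each hit nominates a
candidate overlap which is verified by banded edit-distance alignment of
the full suffix against the equally long prefix.  The suffix copy is
discarded on trimming, keeping the prefix copy (whose interior context
saw higher effective coverage during polishing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

from .core import CIRCULAR, NucSequence, logger


@dataclass(frozen=True)
class OverlapResult:
    """Outcome of terminal-overlap detection on one contig."""

    found: bool
    overlap_len: int = 0
    prefix_start: int = 0
    suffix_start: int = 0
    identity: float = 0.0

    def as_dict(self) -> dict:
        return {
            "found": self.found,
            "overlap_len": self.overlap_len,
            "prefix_start": self.prefix_start,
            "suffix_start": self.suffix_start,
            "identity": round(self.identity, 6),
        }


def detect_terminal_overlap(
    contig: NucSequence,
    min_overlap: int = 20,
    max_overlap: int = 2000,
    seed_len: int = 21,
    min_identity: float = 0.95,
) -> OverlapResult:
    """Find the duplicated terminal overlap of a would-be circular contig.

    Candidates are suffixes of length in ``[min_overlap, max_overlap]``
    whose start matches the contig's ``seed_len``-mer prefix exactly;
    each is scored by banded global edit distance against the same-length
    prefix (band = 10% of candidate length, floor 16).  Ties are broken
    toward the longest overlap, then the highest identity.
    """
    s = contig.residues
    n = len(s)
    if n <= 2 * min_overlap:
        raise ValueError(
            f"contig {contig.id!r} length {n} too short for min_overlap {min_overlap}"
        )
    seed = s[: min(seed_len, min_overlap)]  # a seed longer than the shortest
    # admissible overlap could never nominate it
    window_start = max(0, n - max_overlap)
    best: OverlapResult | None = None
    # scan seed hits in the terminal window, longest candidate first
    pos = s.find(seed, max(window_start, 1))
    candidates = []
    while pos != -1:
        candidates.append(pos)
        pos = s.find(seed, pos + 1)
    for suffix_start in candidates:
        k = n - suffix_start
        if k < min_overlap or k > max_overlap:
            continue
        band = max(16, math.ceil(0.1 * k))
        res = edlib.align(s[suffix_start:], s[:k], mode="NW", task="distance", k=band)
        dist = res["editDistance"]
        if dist < 0:  # beyond the band
            continue
        identity = 1.0 - dist / k
        if identity < min_identity:
            continue
        cand = OverlapResult(
            found=True,
            overlap_len=k,
            prefix_start=0,
            suffix_start=suffix_start,
            identity=identity,
        )
        if (
            best is None
            or cand.overlap_len > best.overlap_len
            or (
                cand.overlap_len == best.overlap_len
                and cand.identity > best.identity
            )
        ):
            best = cand
    if best is None:
        return OverlapResult(found=False)
    return best


def trim_overlap(contig: NucSequence, overlap: OverlapResult) -> NucSequence:
    """Drop the duplicated suffix copy; the result is the circular genome."""
    if not overlap.found:
        raise ValueError(
            f"no terminal overlap found on {contig.id!r}; skip trimming and keep "
            "the contig as-is"
        )
    trimmed = contig.residues[: overlap.suffix_start]
    return NucSequence(id=contig.id, residues=trimmed, topology=CIRCULAR)


def qc_assembly_length(seq: NucSequence) -> str:
    """Mitogenome size gate: pass iff strictly between 14 kb and 16 kb."""
    return "pass" if 14000 < len(seq) < 16000 else "fail"


def circularize(
    contig: NucSequence,
    min_overlap: int = 20,
    max_overlap: int = 2000,
    seed_len: int = 21,
    min_identity: float = 0.95,
) -> tuple[NucSequence, OverlapResult]:
    """Detect and trim in one step; no-overlap contigs pass through unchanged."""
    overlap = detect_terminal_overlap(
        contig, min_overlap, max_overlap, seed_len, min_identity
    )
    if not overlap.found:
        logger.warning("%s: no terminal overlap found; emitting unchanged", contig.id)
        return contig, overlap
    return trim_overlap(contig, overlap), overlap
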