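"""Domain types and coordinate conventions.

Everything in the toolkit speaks one coordinate convention: 0-based,
half-open, on the plus strand of the stored sequence.  GFF3's 1-based
closed intervals are converted at the I/O boundary only.

Circular sequences use modular index arithmetic; a feature may wrap the
origin, in which case it is stored with ``start > end`` and ``wrap=True``
(the interval covers ``[start, L) ∪ [0, end)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

from Bio.Seq import Seq

logger = logging.getLogger("mitofinish")

LINEAR = "linear"
CIRCULAR = "circular"

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "control_region")

_ALLOWED = set("ACGTN")
# IUPAC ambiguity codes demoted to N on input normalization.
_AMBIGUITY = set("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase, demote non-N IUPAC ambiguity codes to N.

    Returns the normalized string and the number of demoted symbols.
    Characters outside the IUPAC nucleotide alphabet (gaps, digits, ...)
    raise ``ValueError`` — they indicate a malformed or aligned FASTA.
    """
    up = raw.upper()
    n_demoted = 0
    out = []
    for ch in up:
        if ch in _ALLOWED:
            out.append(ch)
        elif ch in _AMBIGUITY:
            out.append("N")
            n_demoted += 1
        elif ch == "U":
            out.append("T")
        else:
            raise ValueError(f"illegal residue character {ch!r}")
    return "".join(out), n_demoted


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence with linear or circular topology."""

    id: str
    residues: str
    topology: str = LINEAR

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.topology not in (LINEAR, CIRCULAR):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def circular(self) -> bool:
        return self.topology == CIRCULAR

    def with_residues(self, residues: str) -> "NucSequence":
        return replace(self, residues=residues)

    def reverse_complement(self) -> "NucSequence":
        return replace(self, residues=revcomp(self.residues))

    def rotated(self, offset: int) -> "NucSequence":
        """Rotation so that position ``offset`` becomes position 0.

        Only meaningful for circular topology.
        """
        if not self.circular:
            raise ValueError("rotation requires circular topology")
        off = offset % len(self)
        return replace(self, residues=self.residues[off:] + self.residues[:off])


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    residues: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.residues):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} bases"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Feature:
    """An annotated gene interval on a stored sequence.

    ``start``/``end`` are 0-based half-open on the plus strand of the
    stored orientation.  ``wrap=True`` marks an origin-spanning feature on
    a circular sequence, stored with ``start > end``.
    """

    seq_id: str
    name: str
    ftype: str
    start: int
    end: int
    strand: str
    transl_table: int = 5
    wrap: bool = False

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in feature {self.name!r}")
        if not self.wrap and self.end <= self.start:
            raise ValueError(
                f"feature {self.name!r}: end {self.end} <= start {self.start} "
                "(non-wrapping features need start < end)"
            )
        if self.wrap and self.end > self.start:
            raise ValueError(
                f"feature {self.name!r}: wrap=True requires start > end"
            )

    def length(self, seq_len: int | None = None) -> int:
        if not self.wrap:
            return self.end - self.start
        if seq_len is None:
            raise ValueError("wrap feature length needs the sequence length")
        return seq_len - self.start + self.end

    def extract(self, seq: NucSequence) -> str:
        """Strand-aware subsequence of the feature (5'→3' of the gene)."""
        if self.wrap:
            if not seq.circular:
                raise ValueError(
                    f"feature {self.name!r} wraps but {seq.id!r} is linear"
                )
            sub = seq.residues[self.start:] + seq.residues[: self.end]
        else:
            sub = seq.residues[self.start : self.end]
        return revcomp(sub) if self.strand == "-" else sub


@dataclass(frozen=True)
class DepthTrack:
    """Per-position read depth aligned to one sequence."""

    seq_id: str
    depth: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depth):
            raise ValueError("negative depth value")

    def __len__(self) -> int:
        return len(self.depth)


def homopolymer_runs(s: str) -> Iterator[tuple[int, int, str]]:
    """Maximal single-base runs of *s* as (start, end, base), end exclusive."""
    i, n = 0, len(s)
    while i < n:
        j = i + 1
        while j < n and s[j] == s[i]:
            j += 1
        yield i, j, s[i]
        i = j


def translate(cds_seq: str, table: int = 5) -> str:
    """Translate a nucleotide string (trailing partial codon dropped)."""
    usable = len(cds_seq) - len(cds_seq) % 3
    return str(Seq(cds_seq[:usable]).translate(table=table))
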