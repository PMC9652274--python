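"""Whole-mitogenome pairwise identity and species delimitation.

Identity is computed from the same anchored global alignment used for
concordance: matches divided by alignment columns, where columns exclude
terminal gap runs (length differences at the ends do not count against
identity) but include internal gaps.  The delimitation rule treats a
pair as conspecific when identity is strictly above the cutoff
(default 95%), the threshold established for whole-mitogenome pairwise
comparison of ticks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .concordance import align_assemblies
from .core import NucSequence

SAME_SPECIES = "same_species"
DIFFERENT_SPECIES = "different_species"


@dataclass(frozen=True)
class IdentityResult:
    id_a: str
    id_b: str
    alignment_columns: int
    matches: int
    identity_pct: float
    cutoff_pct: float | None = None
    verdict: str | None = None

    def as_dict(self) -> dict:
        return {
            "id_a": self.id_a,
            "id_b": self.id_b,
            "alignment_columns": self.alignment_columns,
            "matches": self.matches,
            "identity_pct": round(self.identity_pct, 4),
            "cutoff_pct": self.cutoff_pct,
            "verdict": self.verdict,
        }


def _trim_terminal_gaps(ops: tuple[tuple[str, int], ...]) -> tuple[tuple[str, int], ...]:
    start, end = 0, len(ops)
    while start < end and ops[start][0] in ("I", "D"):
        start += 1
    while end > start and ops[end - 1][0] in ("I", "D"):
        end -= 1
    return ops[start:end]


def pairwise_identity(
    a: NucSequence, b: NucSequence, circular: bool = True
) -> IdentityResult:
    """Percent identity over alignment columns (terminal gaps excluded)."""
    aln = align_assemblies(a, b, circular=circular)
    ops = _trim_terminal_gaps(aln.ops)
    columns = sum(n for _, n in ops)
    matches = sum(n for op, n in ops if op == "=")
    if columns == 0:
        raise ValueError("alignment has no columns after terminal-gap trimming")
    return IdentityResult(
        id_a=a.id,
        id_b=b.id,
        alignment_columns=columns,
        matches=matches,
        identity_pct=100.0 * matches / columns,
    )


def delimit_species(result: IdentityResult, cutoff_pct: float = 95.0) -> IdentityResult:
    """Apply the strict >cutoff conspecificity rule."""
    verdict = SAME_SPECIES if result.identity_pct > cutoff_pct else DIFFERENT_SPECIES
    return replace(result, cutoff_pct=cutoff_pct, verdict=verdict)
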