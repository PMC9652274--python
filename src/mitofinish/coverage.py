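"""Coverage masking, depth summaries, and raw-read filtering.

Amplicon ends with poor read support (< 60x in the study conditions this
toolkit targets) are unreliable; masking replaces them with N so that
downstream concordance can exclude them unambiguously.  ``mode="flanks"``
restricts masking to low-depth runs that touch the terminal
``flank_window`` positions — the amplicon ends — while ``mode="any"``
masks every sub-threshold run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import fmean

from .core import DepthTrack, NucSequence, Read


@dataclass(frozen=True)
class MaskSet:
    seq_id: str
    intervals: tuple[tuple[int, int], ...]
    threshold: int
    mode: str

    def covers(self, start: int, end: int) -> bool:
        """True if [start, end) intersects any masked interval."""
        return any(s < end and start < e for s, e in self.intervals)

    @property
    def n_masked(self) -> int:
        return sum(e - s for s, e in self.intervals)


def low_coverage_runs(depth: DepthTrack, threshold: int) -> list[tuple[int, int]]:
    """Maximal runs of positions with depth strictly below *threshold*."""
    runs = []
    i, n = 0, len(depth)
    while i < n:
        if depth.depth[i] < threshold:
            j = i + 1
            while j < n and depth.depth[j] < threshold:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def mask_low_coverage(
    seq: NucSequence,
    depth: DepthTrack,
    threshold: int = 60,
    mode: str = "flanks",
    flank_window: int = 1000,
) -> tuple[NucSequence, MaskSet]:
    if len(depth) != len(seq):
        raise ValueError(
            f"depth track length {len(depth)} != sequence length {len(seq)}"
        )
    if mode not in ("flanks", "any"):
        raise ValueError(f"unknown mask mode {mode!r}")
    runs = low_coverage_runs(depth, threshold)
    if mode == "flanks":
        n = len(seq)
        runs = [
            (s, e) for s, e in runs if s < flank_window or e > n - flank_window
        ]
    residues = list(seq.residues)
    for s, e in runs:
        residues[s:e] = "N" * (e - s)
    masked = seq.with_residues("".join(residues))
    return masked, MaskSet(
        seq_id=seq.id, intervals=tuple(runs), threshold=threshold, mode=mode
    )


def depth_summary(depth: DepthTrack, threshold: int = 60) -> dict:
    if len(depth) == 0:
        raise ValueError("empty depth track")
    vals = depth.depth
    below = sum(1 for d in vals if d < threshold)
    return {
        "mean": fmean(vals),
        "min": min(vals),
        "max": max(vals),
        "fraction_below": below / len(vals),
        "threshold": threshold,
    }


def read_accuracy_quality(read: Read) -> float:
    """Mean read accuracy on the Phred scale.

    -10*log10(mean per-base error probability): the long-read filtering
    convention, dominated by the worst bases.
    """
    err = fmean(10 ** (-q / 10) for q in read.qualities)
    return -10 * math.log10(err) if err > 0 else math.inf


def filter_reads(
    reads: list[Read],
    min_len: int = 500,
    max_len: int = 17500,
    min_q: int = 10,
    mean_of_q: bool = False,
) -> tuple[list[Read], dict]:
    """Length/quality filter for raw long reads.

    Keeps reads with ``min_len <= length <= max_len`` and read quality
    >= ``min_q`` ("less than" thresholds reject, so the boundaries pass).
    ``mean_of_q`` switches to the arithmetic mean of per-base Phred
    scores instead of error-probability averaging.
    """
    kept = []
    report = {"input": len(reads), "too_short": 0, "too_long": 0, "low_quality": 0}
    for r in reads:
        if len(r) < min_len:
            report["too_short"] += 1
            continue
        if len(r) > max_len:
            report["too_long"] += 1
            continue
        q = fmean(r.qualities) if mean_of_q else read_accuracy_quality(r)
        if q < min_q:
            report["low_quality"] += 1
            continue
        kept.append(r)
    report["kept"] = len(kept)
    return kept, report
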