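"""Low-coverage masking and raw-read filtering.

Amplicon ends with read depth below 60x are unreliable and are replaced
with N; raw reads are kept only between 500 bp and 17.5 kb at mean read
accuracy quality >= Q10.
"""

from mitofinish import (
    Read,
    depth_summary,
    filter_reads,
    make_genome,
    mask_low_coverage,
    simulate_depth,
)

genome, _ = make_genome(seed=5)
depth = simulate_depth(len(genome), baseline=300, low_intervals=((0, 150),),
                       low_value=20, seed=6)
summary = depth_summary(depth, threshold=60)
print(f"depth: mean {summary['mean']:.0f}x, min {summary['min']}x, "
      f"{summary['fraction_below']:.3%} of positions below 60x")

masked, maskset = mask_low_coverage(genome, depth, threshold=60, mode="flanks")
print(f"masked intervals: {maskset.intervals} ({maskset.n_masked} nt -> N)")

reads = [
    Read("short", "A" * 400, (30,) * 400),
    Read("long", "A" * 18000, (30,) * 18000),
    Read("lowq", "A" * 1000, (5,) * 1000),
    Read("good", "A" * 1500, (15,) * 1500),
]
kept, report = filter_reads(reads)
print(f"read filter: kept {report['kept']}/{report['input']} "
      f"(short {report['too_short']}, long {report['too_long']}, "
      f"low-quality {report['low_quality']})")
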