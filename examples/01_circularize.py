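"""Trim the duplicated terminal overlap from an assembler contig.

A linear contig of a circular molecule repeats its first bases at the
end; detection must recover the planted overlap length exactly.
"""

from mitofinish import detect_terminal_overlap, linearize_with_overlap, make_genome
from mitofinish import qc_assembly_length, trim_overlap

genome, _ = make_genome(seed=1)
contig = linearize_with_overlap(genome, rotation=4000, overlap_len=300)
print(f"contig: {len(contig)} nt (genome {len(genome)} nt + 300 nt duplicated)")

result = detect_terminal_overlap(contig)
print(f"overlap found: {result.overlap_len} nt at identity {result.identity:.3f}")

trimmed = trim_overlap(contig, result)
print(f"trimmed: {len(trimmed)} nt, topology={trimmed.topology}, "
      f"length QC: {qc_assembly_length(trimmed)}")
# the trimmed sequence is the circular genome again, rotated by 4000:
assert trimmed.residues in genome.residues + genome.residues
print("trimmed sequence is a rotation of the true circular genome")
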