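"""Rotate a circular assembly so the methionine tRNA starts at position 0.

Mitogenomes are published anchored at trnM in plus sense; the anchor is
located by edit-distance search on both strands across the origin, and
feature annotations are re-mapped through the rotation.
"""

from mitofinish import NucSequence, orient, simulate_bundle

bundle = simulate_bundle(seed=2, n_deletions=0)
# rotate the genome away from its published frame to mimic assembler output
rotated = NucSequence(bundle.genome.id, bundle.genome.rotated(6200).residues, "circular")

out, feats, hit = orient(rotated, bundle.anchor)
print(f"anchor located at {hit.position} on {hit.strand} strand "
      f"({hit.mismatches} mismatches)")
print(f"reoriented start: {out.residues[:30]}...")
print(f"anchor sequence:  {bundle.anchor.residues[:30]}...")
assert out.residues == bundle.genome.residues
print("reoriented sequence equals the published-frame genome exactly")
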