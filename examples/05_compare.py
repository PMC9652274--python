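"""Concordance of a query assembly against a reference.

The aligner synchronizes strand and rotation of the circular query,
aligns end-to-end, classifies each difference (type, homopolymer
association) and reports accuracy = 100 * (1 - diff bases / ref length).
"""

import numpy as np

from mitofinish import NucSequence, compare_assemblies, error_profile, make_genome

ref, _ = make_genome(seed=7)

# query: the same genome, rotated, reverse-complemented, with a deletion in
# a homopolymer run and two substitutions
res = list(ref.rotated(3000).residues)
for i in range(len(res) - 4):
    if len(set(res[i : i + 4])) == 1 and res[i] in "AT":
        del res[i]  # one homopolymer deletion
        break
res[500] = {"A": "C", "C": "A", "G": "T", "T": "G"}[res[500]]
res[9000] = {"A": "C", "C": "A", "G": "T", "T": "G"}[res[9000]]
from mitofinish.core import revcomp
query = NucSequence("query", revcomp("".join(res)), "circular")

report, diffs = compare_assemblies(ref, query)
print(f"synchronized: strand {report.query_strand}, rotation {report.query_rotation}")
print(f"differences: {report.counts} ({report.total_diff_bases} bases)")
print(f"accuracy: {report.accuracy_pct:.4f}%")
print(f"homopolymer-associated fraction: {report.homopolymer_fraction:.2f}")
print(error_profile(diffs))
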