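# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mitofinish`, in the order the pipeline applies them.

## Coordinates and sequence model

All internal coordinates are 0-based half-open on the plus strand of the
stored sequence; GFF3's 1-based closed intervals are converted at the
I/O boundary only.  On circular sequences a feature may span the origin;
it is kept as a single record with `wrap=True` (stored `start > end`)
rather than split, because rotation must re-map it atomically.  GFF3
cannot express such an interval, so the GFF3 writer splits wrapped
features into two records sharing an ID; the internal TSV dialect keeps
them lossless.  Input residues are normalized once: lowercase is
uppercased, `U` becomes `T`, and IUPAC ambiguity codes other than `N`
are demoted to `N` with a logged count (finished mitogenome assemblies
are plain ACGT; demotion is a warning, not an error).  Gap characters
are rejected — they indicate an aligned FASTA passed by mistake.

## Circularization

An assembler that walks past the origin of a circular molecule emits
`rot(G) + rot(G)[0:k]`.  Detection is seed-and-extend: the exact
21-mer prefix of the contig (capped at `min_overlap` when that is
shorter) is located in the terminal `max_overlap` window; every hit
nominates a candidate overlap of length k = contig length − hit
position, verified by banded global edit distance (band 10% of k,
floor 16) against the same-length prefix.  Candidates must satisfy
`min_overlap <= k <= max_overlap` (defaults 20 and 2000) and identity
>= 0.95, the toolkit-wide identity floor.  Ties prefer the longest
overlap, then the highest identity: the true junction duplication is
maximal.  Trimming keeps the prefix copy and drops the suffix copy — an
arbitrary but fixed choice, documented because it decides which
polished bases survive.  A contig without a qualifying overlap is
passed through unchanged with a warning; downstream steps still work on
it as a circle.  The length gate accepts assemblies strictly between
14,000 and 16,000 nt, the plausible size window for a complete tick
mitogenome.

Using an exact seed means an overlap whose first seed-length bases were
corrupted by polishing errors is missed; at polish-level error rates
this is rare, and the identity verification tolerates errors anywhere
else in the overlap.

## Orientation

The anchor (20–120 nt, typically a ~64 nt methionine tRNA from a close
relative) is searched by edit distance over the doubled sequence — so
occurrences crossing the origin are found — on both strands, with up to
`ceil(0.25 · |anchor|)` edits.  The 0.25 default allows for divergence
between the specimen and the relative donating the anchor.  Equal-best
hits at distinct sites raise an error rather than tie-breaking:
a silently mis-oriented assembly corrupts every downstream comparison.
Reports of the same site that differ only by an indel in the alignment
start are collapsed before the ambiguity check.  Rotation re-maps every
feature (`start' = (start − rot) mod L`), recomputing wrap flags;
reverse complementing maps `[s, e)` to `[L−e, L−s)` and flips strands.
Both transforms preserve each feature's strand-aware extracted
sequence, which the tests assert directly.

## Frameshift repair

Premature stops are found by strand-aware extraction and translation
under the feature's genetic code (default table 5, invertebrate
mitochondrial, stops TAA/TAG); every full codon strictly before the
final codon counts, and the final codon is exempt even when truncated
(mitochondrial CDSs commonly end in an incomplete T/TA stop completed
by polyadenylation).

For each premature stop the candidate homopolymers are maximal A/T runs
inside the CDS upstream of the stop (gene coordinates `[0, 3·stop)`),
ordered nearest-to-stop first — the error and its stop are usually
adjacent.  Two thresholds are tried in order: runs >= `min_run` (8, the
length class in which nanopore deletion errors concentrate), then runs
>= `fallback_min_run` (3, the general homopolymer definition of any
span of one nucleotide > 2).  One copy of the run's base is inserted at
the run's 3' end in gene orientation — within a homopolymer every
insertion point yields the same sequence, so a fixed choice makes the
output deterministic.  An insertion is accepted iff it removes that
stop without creating an earlier one; up to 3 edits per gene are tried,
and genes that remain broken are reported `resolved=False`, never
dropped.  All feature coordinates shift by +1 per accepted insertion.

Only single-base insertions into CDS intervals are automated.
Substitution or deletion edits, start-codon repair, and larger
deletions (which need supporting read pileups) are out of scope; tRNA
and rRNA sequences are never edited.  When a gene contains several
equal-base runs upstream of a stop the nearest one is tried first; if a
more distant run was the true error site, an accepted nearer insertion
can yield a stop-free but non-truth protein.  With unique long runs per
gene — the situation the simulator produces and the dominant case in
real data — repair is exact.

## Coverage QC and read filtering

Masking computes maximal runs of positions with depth strictly below
the threshold (default 60x).  `mode="flanks"` masks only runs touching
the first or last `flank_window` (1000) positions — the amplicon ends,
where coverage loss concentrates; `mode="any"` masks every run.  Masked
positions become `N` (not soft-masked), so concordance can exclude them
unambiguously; length is conserved and unmasked positions are
byte-identical.

Read filtering keeps reads with 500 <= length <= 17,500 and read
quality >= 10, where read quality is −10·log10(mean per-base error
probability) — the long-read convention, dominated by the worst bases.
The arithmetic mean of Phred scores is available behind a flag.
Thresholds are "less than removes", so boundary values pass.

## Concordance alignment

Global alignment of two ~15 kb assemblies is made desk-fast by anchor
chaining: 15-mers unique in both sequences are matched, co-diagonal
runs merged into segments, and the heaviest strictly co-linear chain
selected; anchors align by construction and the regions between them
are aligned exactly by affine-gap DP (Gotoh) with deterministic
traceback (diagonal, then deletion, then insertion on ties).  Scoring:
match +1, mismatch −2, a gap run of length L costs 4 + L (open −4,
extend −1, the first gap base paying both).  Regions larger than
250,000 DP cells are re-anchored recursively with k-mers unique
*within the region* (sparse global anchors are common in A/T-rich
stretches but locally unique 15-mers are plentiful); a region with no
local anchors at all falls back to a unit-cost optimal edit path.
Oracle tests compare the anchored aligner's total differing bases
against an exhaustive full-DP aligner (Biopython's `PairwiseAligner`
under the same scoring) on random pairs.

Circular queries are synchronized first: the strand with more shared
unique anchors is chosen, then anchor offsets `(q − r) mod L` are
clustered circularly (single linkage, tolerance max(64, L/20)) and the
dominant cluster fixes the rotation, taken from its smallest-ref-
position anchor so the alignment starts at the shared origin.  The
modal offset alone is not robust: an interior deletion splits offsets
into adjacent bins and can out-vote the origin-true offset.

Adjacent alignment columns of one edit type merge into a single
difference event.  Events are counted in bases (an n-base indel
contributes n).  An event is homopolymer-associated when the reference
run of the inserted/deleted base touching the site — or, for
substitutions, the run containing it — has length >= 3 (the "> 2"
homopolymer definition); multi-base events of mixed bases are not.
A difference is in-mask when its reference interval intersects a masked
interval (insertions: when either flanking reference base is masked).
Accuracy is `100·(1 − D/L_ref)`, optionally excluding in-mask events;
the error profile is the event count cross-tabulation of type ×
homopolymer association.

Because event merging conventions differ between comparison tools,
per-event counts may differ from other difference callers even when
total differing bases agree; the accuracy statistic depends only on the
total.

## Identity and delimitation

Pairwise identity reuses the concordance aligner: matches divided by
alignment columns, where columns include internal gaps but exclude
terminal gap runs, so length differences at the ends do not count
against identity.  Other tools' undocumented denominator conventions
can differ in the last decimal; this one is fixed and tested, including
the boundary cases.  The delimitation verdict is conspecific iff
identity is strictly greater than the cutoff (default 95%).

## Synthetic data

The generator emulates the inputs the pipeline sees in the study
conditions it targets: ~15 kb circular genomes at A/T fraction 0.75
(tick mitogenomes are A/T-rich; the exact composition is a fixture
choice, not a biological claim), with 13 CDSs of typical mitochondrial
gene lengths, 22 tRNAs (trnM first, at position 0, plus sense — the
publication convention orientation restores), 2 rRNAs, and one control
region (groupB organization) or two (groupA), the control region(s)
absorbing the remaining length.  The fixed gene complement needs about
14.4 kb, so requested lengths below ~14.5 kb are rejected as infeasible
geometry.

CDSs are valid table-5 ORFs (ATG start, stop-free body, TAA stop).
Background codons exclude the stops and the two single-codon
homopolymer builders AAA/TTT, which caps background A/T runs inside a
CDS at 4 nt; each CDS then gets one explicitly planted AAA/TTT codon
block (run of 9 or 12).  This makes every planted run the unique run
>= 8 of its gene, so the expected repair is unambiguous and recovery
can be asserted byte-identically.  Deletion injection only uses runs
whose deletion provably produces a premature stop (verified by
translation at injection time) and picks one run per gene.

Contigs are built as `rot(G') + rot(G')[0:k]` with optional
substitution errors in the overlap copy; depth tracks are a constant
baseline (default 300x) with ±10% multiplicative jitter and planted
low-coverage windows.  Every generator output is a pure function of its
arguments including the seed.

What the simulator does **not** model: read-level error processes (it
plants clean, isolated edits rather than polisher-correlated error
tracts), real tick gene order and tRNA/rRNA secondary structure,
control-region repeats, and reference assemblies with their own errors.
Passing tests therefore demonstrate the correctness of the finishing
computations under controlled error models, not end-to-end accuracy on
real sequencing data.

## Problem sizes and determinism

The test suite and the acceptance script run the methods at the sizes
the properties are stated for: 50 genomes for circularization
round-trips, 20 genomes / 100 planted deletions for frameshift
recovery, 200 random pairs (<= 300 nt, ~5% edit rate) for the
alignment oracle, full ~15 kb genomes for identity and pipeline runs.
Everything completes in seconds on one CPU.  All randomness flows
through explicit integer seeds; the CLI writes reports with sorted keys
and no timestamps, so identical inputs produce byte-identical outputs,
which the determinism test asserts.
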