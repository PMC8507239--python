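# Methods

This note documents the models, estimators and numerical choices behind
`sagbin`, what the synthetic data does and does not emulate, and the design
decisions taken where more than one reading was defensible.

## Alignment substrate

Every similarity computation in the package (ANI, marker detection, chimera
mapping, binning, merging, coverage) runs on one local aligner
(`sagbin.pairwise`). It is a seed–chain–extend design tuned for the
near-identity regime the workflow operates in (≥ 90% identity within a
strain group, > 99% for binning evidence), not a sensitive homology search:

- **Seeding.** Exact k-mer matches against a single-strand sorted-array
  index (k = 15 for contig queries, k = 13 for reads; k-mers containing N
  are not indexed, and contigs are concatenated with k·N separators so no
  seed spans a boundary). Reverse-complement hits come from looking up the
  reverse-complemented query.
- **Chaining.** Seeds chain when they share a target contig and a diagonal
  band (drift ≤ 50 bp) and successive query positions gap by ≤ 500 bp.
  These budgets deliberately reject distant homology.
- **Extension.** Gap-free X-drop extension (match +1, mismatch −2, drop 20)
  from both chain ends, reporting the best-scoring endpoint. Stopping at
  the score maximum trims terminal mismatch runs, which is what keeps
  chimera-junction estimates within a few bases of the truth.
- **Scoring.** Identity is recomputed from the full edit path of the final
  block (edlib), as matches / aligned columns with gaps in the denominator
  (the blastn convention). It is never estimated from seed counts.
- **Pruning.** Overlapping blocks on the same *target* interval (> 50% of
  the shorter) are pruned keeping the highest identity × length: one
  evidence unit per target locus. Pruning on the target side rather than
  the query side is essential for copy-number counting — a duplicated locus
  yields two blocks from the same query region and both must survive.

Tests hold the block identity to within 0.5 percentage points of an
independent dynamic-programming oracle (Biopython's `PairwiseAligner`) on
sequences up to ~5 kb.

## Genome comparison

**TNF.** 136-dimensional canonical (reverse-complement-collapsed)
tetranucleotide frequencies over all N-free windows, compared by Pearson
correlation. On i.i.d. random sequences the TNF signature mostly reflects
base composition, so same-GC genomes correlate highly; the > 0.90 grouping
criterion is therefore treated as a necessary, cheap gate (evaluated
first), never as sufficient evidence.

**ANI.** Fragment-mean in the FastANI style: the query is chopped into
3 kb windows (terminal window kept if ≥ 1.5 kb); a fragment is *mapped*
when its best block covers at least half the fragment at ≥ 80% identity;
ANI = 100 × mean identity over mapped fragments, undefined below 5 mapped
fragments. The half-fragment floor stops a shared 1 kb marker or rRNA token
from making two otherwise unrelated genomes look comparable, and the
minimum support keeps conserved-token-only hits from defining an ANI at
all. Calibration on seeded substitution models holds the estimate within
±0.5 points of 100·(1−m) for m ∈ {1, 3, 5}%.

**Marker homology and quality.** The completeness/contamination estimator
consumes a user-supplied set of single-copy marker sequences: completeness
= % of markers found (≥ 80% identity over ≥ 50% of length), contamination
= extra non-overlapping copies / marker count. Marker homology between two
assemblies compares the best extracted copy from each with an *infix*
alignment (the shorter inside the longer), so a copy truncated at an
assembly gap is scored over its aligned span rather than charged for the
missing remainder — with a global alignment, two fragmentary SAGs of the
same strain scored ~95% homology and same-strain grouping collapsed.

## Strain grouping and chimera cleaning

Grouping admits a pair on ANI > 95 ∧ homology > 99 ∧ TNF > 0.90 (strict
inequalities; undefined ANI or homology fails) and takes connected
components (single linkage). The evaluation short-circuits: TNF first, ANI
next, homology last; skipping later criteria for a failed pair cannot
change the result.

Chimeric reads are split by cross-reference mapping within the group: a
read whose best single mapping covers < 90% of its length with a ≥ 30 bp
anchor is cut at the mapped boundary; fragments < 20 bp are discarded; only
newly produced flanks are re-mapped in later cycles (3 by default). Reads
are mapped against *all* member assemblies **including the read's own SAG**:
a genuine read always maps full-length to its own assembly, so partial hits
caused by another member's dropout boundary never trigger a split, and with
no chimeras present no read is ever split. The trigger consequently fires
only when even the read's own assembly cannot explain it end-to-end — which
is exactly a junction artifact under this data model (the simulator builds
SAG assemblies from the true retained regions, not from the reads; a real
assembly could itself contain a chimeric contig and mask the read that
produced it).

The bundled co-assembler exists so the pipeline runs with no external
binary: greedy longest-exact-suffix–prefix-overlap merging (≥ 40 bp),
implemented as a one-pass union-find over precomputed read-to-read overlap
edges (a merge never changes the outer ends of a chain, so edges never need
recomputation). Exact duplicate reads are removed first; containments are
not merged and fall below the 1 kb contig floor. Error-free tiled reads
reconstruct their template exactly; any external assembler can be plugged
in as a callable. nrSAG dereplication keeps the most complete candidate
among survivors at pairwise ANI ≥ 99.5% — the same identity level used for
closest-reference assignment, adopted here as the dereplication cutoff.

## Guided binning

Winner-take-all on summed qualifying aligned length (identity > 0.99,
length > 200 bp, both strict), blocks on all contigs of one nrSAG summed so
nrSAG fragmentation is not penalized; ties break by higher mean identity,
then lexicographic nrSAG id, making assignment deterministic under input
permutation. A contig joins at most one bin by construction. The known
failure mode is intrinsic to identity-threshold guidance: between strains
at ~98.5% ANI, a short contig with above-average local conservation (or a
shared verbatim element) can clear the 99% bar against the wrong strain
when its own nrSAG lacks the region; the worked example in the README shows
one such contig.

## Guided merging

The more complete side is primary (tie → nrSAG, so the draft is labeled
mgSAG); the secondary is filtered to contigs ≥ 10 kb (a 10,000 bp contig is
kept — removal is "strictly shorter"). Each secondary contig then meets one
of three fates: **dropped** when ≥ 95% of its length aligns to the primary
*and* it carries < 100 bp of novel sequence; **end extension** when a
≥ 1 kb block reaches a primary contig end (± 100 bp) — the contig is
extended with the secondary's *unaligned* overhang only, trimmed at the
next aligned interval, so a contig bridging a gap between two primary
contigs plugs the gap without duplicating the far side, and one secondary
contig may plug several gaps (each unaligned interval claimed once);
**appended** when nothing aligns. A mostly-aligned contig offering no end
extension is dropped rather than appended — appending it would duplicate
aligned sequence. The absolute 100 bp novelty floor matters: a 120 bp 5S
gene inside a 40 kb secondary contig is 99.7% "contained" by the relative
rule alone and would be unrecoverable. Merging never deletes primary
sequence and is idempotent.

rRNA genes are counted by alignment to class reference sequences at ≥ 90%
identity with per-class aligned-length floors of 700 bp (16S), 1100 bp
(23S) and 80 bp (5S — the two long floors are the published detection
thresholds; 5S at ~120 bp needs some floor and 80 bp is adopted here).
tRNAs are read from an external annotation table only; no detector is
bundled, and an absent annotation counts 0 with a warning.

## Evaluation

`length(A_i ∩ G_g)` is read as the **draft-side** aligned length (union of
draft intervals aligned at ≥ 90% identity to the assigned reference): since
precision divides by the draft length, this guarantees P ≤ 1 structurally,
and duplicated draft sequence aligning twice depresses recall, not
precision. The interval-union computation is held exactly equal to a
per-base boolean counter in tests. Closest-reference assignment requires
ANI ≥ 99.5% or the draft stays unassigned; bins whose anchor assembly is
unassigned have all truth-labeled members counted as incorrectly binned
(conservative).

## Synthetic community model

The generator emulates, per species: a random chromosome at GC drawn from
[0.3, 0.7]; 40 single-copy 1 kb marker genes implanted at random
non-overlapping loci (species variants diverge 3% from a canonical set, so
cross-species marker homology sits near 94%); one 5S/16S/23S token each
(120/1550/2900 bp, also 3% diverged per species — conserved but not
identical). A strain pair copies the chromosome and applies uniform
substitutions; the rate outside implanted elements is rescaled so the
*genome-wide* divergence equals the requested value, making generated pair
ANI land within ±0.3 points of 100·(1−d). Markers stay verbatim between
strains by default; a configurable marker SNP rate mutates them (with the
genome-wide rate re-balanced) to exercise the homology criterion — the
pipeline profile enables it at the strain divergence rate, since real
strains carry SNPs in marker genes too and without them the grouping
criteria cannot tell a 98.5%-ANI pair apart. Strain-specific plasmids are
independent random sequences flagged in the truth tables.

SAG simulation deletes random fixed-size windows (default 5 kb, the scale
of amplification dropout) until the retained fraction reaches the
completeness target, assembles the retained segments (≥ 1 kb) and tiles
error-free reads at the requested depth; a chimera fraction of reads are
junction-joins of two retained loci with the junction recorded. Because the
window removal order is a fixed shuffled grid, lowering the target removes
a superset of windows — the completeness sweep is nested by construction,
which is what makes the unbinned-vs-completeness relationship exactly
monotone rather than monotone in expectation. The metagenome is simulated
directly at contig level (lengths ~ Normal(20 kb, 5 kb), floor 1 kb,
strain-pure by default, with optional consensus mixing of variant sites and
abundance-dependent fragment loss); assembling metagenomic reads is outside
the model.

Not emulated: sequencing errors and quality scores, GC-dependent
amplification bias, rRNA operon structure and real marker gene families,
inter-genome repeats, uneven coverage within a genome. Passing tests
therefore demonstrate the correctness and calibration of the workflow's
logic under a clean substitution-and-dropout model, not performance on real
reads; on real data the alignment thresholds absorb sequencing error, and
assembler choice dominates CoSAG quality.

## Problem sizes and determinism

The standard benchmark scenarios use 10–11 genomes of 200 kb (binning),
200 kb strain pairs (resolution), 100 kb sweeps, and 30–100 kb calibration
genomes — large enough that fragment-ANI has ≥ 30 fragments of support and
marker statistics are stable, small enough that the whole benchmark suite
runs in minutes on one CPU. All randomness flows through explicit integer
seeds (numpy `SeedSequence` spawning, derived seeds kept below 2³¹); a
fixed seed reproduces every FASTA/TSV byte-for-byte, and the pipeline
writes a manifest of SHA-256 digests plus a run log with the resolved
configuration.

## Known limitations

- One bin per contig: sequence shared between strains follows the summed-
  length winner; multi-assignment is deliberately not implemented.
- The greedy co-assembler requires exact overlaps and is only adequate for
  the error-free simulated reads; real reads need an external assembler.
- The marker estimator is relative to the supplied marker set; it is not a
  lineage-aware checker, and absolute completeness values depend on the
  set's coverage of the genome.
- Guided merging never rearranges or corrects primary contigs; misjoins in
  the primary survive merging.
- Strain discrimination degrades as pair ANI approaches the 99% binning
  identity threshold; short conserved contigs are the first casualties.
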