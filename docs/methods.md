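# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `vdjlineage`. Coordinates are 1-based and inclusive
throughout.

## Alignment model

Germline genes are placed against reads ungapped. Each placement
(offset) is scored on its match/mismatch pattern by the consecutive-run
score `Σ Cᵢ² − Σ Mⱼ²`. The quadratic run weighting rewards long exact
stretches far more than the same number of matches scattered among
mismatches, which is what distinguishes a genuine germline segment from
chance similarity in the short V(D)J junction.

**Mismatch leniency.** Somatic hypermutation (SHM) peppers genuine
segments with isolated substitutions. Up to a budget of *isolated*
mismatches (runs of exactly 1) may be forgiven: a forgiven position
contributes zero length but fuses its flanking match runs into a single
squared term. Runs of two or more consecutive mismatches are never
forgiven — consecutive mismatches are the signature of a wrong placement
or a junction boundary, not of SHM. The budget is spent greedily from
the 5′ end (SHM is more frequent near the 5′ end of these amplicons);
when the budget cannot cover every isolated mismatch this greedy choice
is the defined semantics, not an optimisation guarantee, and the tests
assert exactly it. A forgiven mismatch at a pattern terminus is allowed
(it contributes zero next to a single flanking run). Ambiguous read
characters (N) always count as hard, unforgivable mismatches.

Budgets: the V segment forgives up to `ceil(0.15 × overlap)` mismatches;
D and J reuse the mutation fraction actually observed on the chosen V of
the same read (`ceil(v_mutation_fraction × overlap)`). Both are
configurable (`AnnotationConfig.v_leniency_fraction`).

**Aligned extent.** For each offset the reported segment is the best
contiguous aligned extent: terminal mismatch runs are removed, and end
blocks (the outermost match run plus the mismatch run separating it from
the body) are greedily dropped while that strictly increases the score.
Rationale: recombination deletes germline gene ends, so aligning the
full gene necessarily drapes a few junk nucleotides over the junction;
forcing them into the segment would corrupt both the segment boundary
and the downstream N regions. Offsets are compared by (score, longer
overlap, smaller offset); gene ties at the top score keep the full tied
list, report the first by (overlap, smaller offset, name), and drop
pseudogene suggestions when functional alternatives tie.

The offset search is exact but pruned: an offset with `m` matching
positions can never exceed `m²`, so offsets are visited in decreasing
match count (computed for all offsets at once by one-hot
cross-correlation) and abandoned once the bound falls below the best
exact score; genes are likewise visited in decreasing best-possible
order with a shared score floor. A test verifies equality with a naive
full scan.

**Minimum overlaps** are 10 nt for V and J and 3 nt for D; the source
algorithm leaves these unstated, so they are explicit configuration.

**V indel correction.** Single-nucleotide sequencing indels in the V
framework (5′ of the 104Cys codon) manifest as a structurally misaligned
tail. The search is triggered only when the V mutation fraction exceeds
0.25 — well above the 15% leniency band, and roughly what a mid-segment
indel produces (half the segment mismatching at ~75%). Up to two edits
(deleting a read base, or inserting any base) are applied, each only if
it raises the V score by more than a margin of +4 *and* reduces the
mismatch count; the second condition rejects "repairs" that merely
extend the overlap with fabricated germline sequence. The region at and
after the 104Cys anchor is never edited, since junction indels can be
genuine recombination products. Margin, cap, and trigger are
configurable and all edits are logged per read.

## Segmentation order and preservation rules

V is matched first, against all but the last 9 nt of the read, so that
short D and J segments cannot be swallowed by an overextended V. After
the V match, 3 nt to its right are reserved before the J match begins;
after J, every nucleotide between V and J is offered to the D match
(inverted, "r"-prefixed reverse-complement D genes included by default).
Unassigned junction nucleotides become the N_VD and N_DJ regions; the
five intervals V | N_VD | D | N_DJ | J always tile the read. The CDR3
runs from the first base of the V 104Cys codon to the last base of the J
118Trp codon, both mapped through the alignment offsets; a read is
productive when the two anchors share a reading frame (junction length
divisible by 3) and that frame is stop-free across the junction. Reads
failing V or J annotation keep their row in the output with a status
column; they are never silently dropped.

## Clustering and lineage trees

Reads are first coarsely grouped by (CDR3 length, V family number, J
family number). Within a group, every sequence links to its nearest
neighbour under the asymmetric SHM distance (run-squared Hamming with
per-mutation weights −0.5 / 0 / +0.5 for favored / neutral / rare
substitutions). Nearest-neighbour ties break by higher template count,
then id. The directed nearest-neighbour map has exactly one cycle per
connected component; the cycle member with the smallest total SHM
distance to the rest becomes the root (ties: higher total VDJ alignment
score, then id) and edges orient away from it.

No distance cutoff is applied to this within-group linkage: a
five-mutation generation step typically costs ~4–5 SHM distance units,
more than 3% of a 125-nt read, so a linkage cutoff would shatter genuine
lineage chains. The 3% cutoff governs the *merge* stage instead: roots
of small trees iteratively attach to the nearest sequence of another
tree whenever the parent-to-root distance (in the adopted direction)
stays within `cutoff_fraction × read length`; merges are processed in
ascending distance order, ties by root id, until none apply. Sequences
of unequal length (possible after an indel correction) are compared over
their common 3′-anchored span, since every read ends on the 118Trp
codon.

After trees are final, each cluster unifies annotations: all members
adopt the root's own V/D/J calls and boundary intervals, the predicted
germline is reconstructed (germline bases over V/D/J, the root's own
bases over the N regions), and each member's mismatches are recounted
against it. The tree is then re-rooted if another member has strictly
fewer raw germline mismatches (raw count, not the weighted distance —
the simpler statistic; ties keep the current root), and unification
repeats from the new root's original annotation.

## Junction refinement

A *consensus mismatch* is a position where 100% of cluster members
mismatch the predicted germline — the signature of a wrong annotation
rather than of SHM, unless one also appears in the V framework (then the
shared mismatches are taken to be genuinely inherited SHM and the
junction is left alone).

**D re-annotation.** Gated on ≥1 CDR3 consensus mismatch and none in the
V framework, every D gene is re-aligned over the junction window of the
root. A candidate replaces the current D only if it (a) strictly reduces
the consensus mismatches inside the D segment, (b) strictly increases
the D alignment score, and (c) strictly increases the total objective
`score_V + score_D + score_J + Nscore(N_VD) + Nscore(N_DJ)`. Condition
(b) resolves an ambiguity in the acceptance rule's phrasing ("increased
the sum of the VDJ alignment scores and the Nscores"): read as one
combined sum, the length-quadratic Nscore lets a candidate pay for a
large alignment-score loss simply by moving templated nucleotides into a
longer N region, which measurably degraded benchmark accuracy; requiring
both parts to improve eliminates that failure mode while preserving the
intended rescues. The combined objective is still guaranteed
non-decreasing across the call.

**N-edge refinement.** Each segment edge abutting an N region (V 3′, D
5′, D 3′, J 5′, processed in that order) is examined once per pass:

* Rule A — a run of ≥3 consecutive consensus mismatches with at most 2
  germline-matching nucleotides between it and the segment tip moves
  into the N region unconditionally, carrying those matching
  nucleotides along.
* Rule B — no N region on that side: the piece from the innermost
  consensus mismatch (within the 4 tip-most nucleotides) through the tip
  is trimmed iff its P_TDT exceeds 0.50.
* Rule C — an N region exists: the piece is trimmed iff the combined
  region's P_TDT strictly exceeds that of the piece alone (this is the
  comparison the worked `gGG`+`ccc` → 0.93 → 0.31 example pins down; a
  comparison against the existing N region instead would accept it).

The D segment is never trimmed below 3 nt and V/J never below 1 nt; the
tiling invariant is restored after each pass. The Step-3/Step-4 pair
runs at most twice and stops early when the consensus set is stable. The
empty N region is defined to have P_TDT = 0.5 (neutral) and Nscore = 0.

## TDT model

Insertion probabilities default to the published healthy-mouse values
P_A=0.25, P_C=0.08, P_G=0.60, P_T=0.07 and are exposed as configuration
(`TDTModel`), not re-estimated from input data. P_TDT is the larger of
the value on the sequence and on its element-wise (non-reversed)
complement; the non-reversed convention is forced by the printed 0.40
for `tATC` (complement `ATAG`). P_TDT is a composition statistic — it is
order-invariant — so only the multiset of nucleotides matters.

## Benchmark simulator

The simulator emits the study conditions used by the recovery tests: by
default 1,000 independent productive recombination events plus a
5-generation hypermutation chain per event (one descendant per round,
6,000 sequences total). Genes are drawn uniformly — the goal is to
exercise VDJ combinations, not to reproduce usage frequencies. Per
event: gene ends lose a truncated-geometric number of nucleotides
(P(d) ∝ 0.55^d, capped at 5; the D remnant never drops below 3 nt since
D-less junctions are out of scope), N regions of uniform 0–8 nt are
drawn i.i.d. from the TDT insertion probabilities with a 50% chance of
element-wise complementation (either-strand elongation), and the
assembly is trimmed to 125 nt ending exactly on the J 118Trp codon.
Junctions with an out-of-frame anchor pair or an in-frame stop codon are
rejected and resampled. Each SHM round substitutes exactly 5
never-before-mutated positions of the previous round's sequence, using a
substitution matrix whose defaults encode the qualitative biases of
affinity maturation (C→T and G→A dominant at 0.6; A mutated more than T;
A→G > A→T > A→C). Everything is driven by one `numpy` generator seeded
from `SimConfig.seed`.

The geometric deletion model (rather than uniform 0–5 per end) is a
deliberate realism choice: uniform deletions leave a large fraction of D
remnants at 3–6 nt, which no annotator can identify against ~24
candidate genes in a ~15-nt junction — a regime inconsistent with the
95%+ germline-level degenerate-D accuracy that this class of algorithm
demonstrably reaches on its published benchmark. With geometric
deletions most remnants stay ≥7 nt and short-remnant events still occur
but no longer dominate.

The synthetic germline database (deterministic per seed) emulates a
mouse heavy-chain locus: 20 V genes of 291 nt ending in a 104Cys codon
plus two trailing codons, 12 D genes of 9–18 nt (plus their inverted
copies), and 5 J genes of 48 nt with a unique in-frame 118Trp codon,
with IMGT-style names, strain tags, and pairwise distinctness of ≥2 nt
over the read-visible portion.

**What the simulator does not model** — and hence what passing tests do
not establish about real data: sequencing error and template-count
noise, indel SHM, gene-usage skew, allele families with ≥98% mutual
identity (real IMGT databases contain many; degenerate matching absorbs
them), position-dependent SHM hot spots (mutated positions are uniform),
repeated mutation of a site within a lineage, and unrelated clones that
genuinely collide in junction space more often than uniform gene draws
imply.

## Evaluation statistics

Gene calls are scored exactly (full allele-name equality) or
degenerately (called and truth allele sequences ≥98% identical over the
best ungapped containment of the shorter in the longer — for short D
genes this effectively requires substring identity). SHM calls are
scored per position as TP/TN/FP/FN with ACC = (TP+TN)/total and
PPR = TP/(TP+FP), defined 0 when nothing is called. SHM propensities are
counted over parent–child tree edges (never germline–child, which would
recount inherited mutations), excluding N regions, row-normalized over
the 12 ordered substitutions; V-vs-DJ consistency is the Pearson r and
regression slope over those 12 frequencies. Hot-spot profiles tabulate
parent-strand composition at offsets ±k around mutated positions *and*
around all positions, because apparent motifs must be judged against the
background composition. No multiple-testing correction is applied
anywhere; all of these are descriptive statistics.

## Problem sizes used by the test suite

The recovery benchmark in the acceptance tests uses 50 clones × 5
generations (300 reads) against the default 20V/12D/5J database with all
seeds fixed at their defaults, and the propensity-correlation check uses
the full 1,000-clone simulation (truth-based, no annotation). These
sizes give binomial standard errors of ~2% on the recovery rates while
keeping the suite fast; the pipeline throughput is roughly 0.5 s per
read on one core, dominated by the V-gene placement search.

## Known limitations

* Double-D (VDDJ) junctions and D-less VJ junctions are not modelled or
  annotated.
* Light chains are out of scope; only heavy-chain loci are handled.
* Clusters can absorb clonally unrelated sequences when two independent
  recombinations land within the merge cutoff; the cutoff is global and
  user-set, not adaptive.
* A wrong D call that happens to match the read junction exactly leaves
  no consensus mismatch and is invisible to refinement ("inherently
  ambiguous" junctions).
* The greedy 5′-first leniency and the greedy end-block extent trimming
  are defined procedures, not global optima.
* Quality scores are ignored; reads are assumed sense-strand and
  junction-spanning (no pair-end merging or orientation fixing).
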