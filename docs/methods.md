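# Methods

## Similarity model

All clustering in this package is driven by one scalar per sequence pair:
the percent identity of an optimal pairwise alignment.  Identity is defined
as identical columns divided by alignment columns, with three alignment
scopes:

* **semiglobal** (default) — an overlap alignment with free end gaps;
  identity = identical columns / max(overlap columns, length of the shorter
  sequence).  End overhangs are not part of the alignment, so a clean
  substring of a longer sequence scores 1.0; internal gap columns count
  against identity.
* **local** — the classic HSP identity: identical columns / columns of the
  best-scoring local alignment (0 when no positive-scoring alignment
  exists).
* **global** — end gaps penalized and counted.

The semiglobal default is a deliberate design choice.  A score-optimal
local alignment of two *weakly* related sequences trims to whatever short
segment happens to be cleanest, so its identity is biased high: measured on
planted data with a true pairwise identity of 0.70, local identities range
up to ~0.92, and across the hundreds of thousands of pairs of a realistic
dataset the maximum crosses any clustering threshold — connected components
then chain unrelated families together.  A plain overlap identity has the
mirror-image defect (a short clean *end* overlap of unrelated sequences can
out-score the full span and report identity ~1).  Dividing by the shorter
sequence length, as the established greedy clustering tools do, removes
both failure modes: a short spurious alignment then contributes few matches
against a full-length denominator.  Thresholds are not portable across
these definitions (or across scoring parameters), which is why every knob
is explicit in `SimilarityParams`.

Scoring defaults: DNA match +1, mismatch −2, gap open −5, gap extend −2
(gap open is the score of the first gap column, extend of each later one);
protein BLOSUM62 with gap open −11, extend −1.  IUPAC ambiguity codes and
N/X are accepted but never count as identities (conservative and
deterministic).  Alignments are computed by Biopython's `PairwiseAligner`;
the pair is put into a canonical order before aligning because traceback
tie-breaks among co-optimal alignments depend on argument order and
similarity must be symmetric.

## Comparison accounting

The cost model of every algorithm is the number of pairwise alignments
performed.  A `ComparisonLedger` counts exactly that: each unordered id
pair is counted once while its cache entry is live, cache hits are free,
and the **f-value** of a run is ledger comparisons ÷ N(N−1)/2.  The cache
also implements the design decision that similarities computed at one MLC
level are reused at later levels rather than recomputed — the f-value is
meant to measure comparisons *needed*, and recomputation is avoidable work.
When a pre-ordering pass (greedy pre-clustering at a low threshold) is
used, its comparisons land on the same ledger and are included in the
f-value.  `half_matrix` evaluates pairs in batches of at most
`ledger.batch_limit` (default 1,000,000, the memory cap used in the
original large-scale runs); batching never affects results, only peak
memory.

## Representatives

A group is ideally represented by its *central* sequence — the member
maximizing the summed similarity to the other members — but that costs a
half matrix of the group.  The *almost-central* sequence bounds this: order
the members by similarity to the group's greedy representative (the anchor,
which ranks first at similarity 1), take k members at evenly spaced ranks
⌈i·n/k⌉ for i = 0 … k−1, and return the centre of that subset (k = 10 by
default, O(k²) alignments).  The spaced ranks are anchored at the *most*
similar member so that k = 1 degenerates to the member closest to the
anchor.  On a group with a dominant core and a minority of stragglers —
what a low-threshold greedy pass actually produces — this reliably moves
the representative from a straggler anchor into the core, which is the
failure mode of "first sequence as representative" that the heuristic
exists to fix.  On a *flat* group (all similarity sums within noise of each
other) the subset centre is only weakly correlated with the exact centre;
that is harmless, because any member of a flat group represents it equally
well.

Ties everywhere (equal similarity sums, equal similarities during
ordering) break by ascending sequence id, making every algorithm
deterministic given its input order.

## The algorithms

* **GC** joins each sequence to the *first* representative (in creation
  order) within threshold — the classic greedy scheme, which is what makes
  it O(N·m).  A best-match mode is available behind a flag.
* **CCBC** computes the full half matrix (in ledger batches) and takes
  connected components via `scipy.sparse.csgraph`.  Cluster representatives
  are almost-central members, found by reading the already-computed matrix
  so a cold-cache run performs exactly N(N−1)/2 comparisons — f = 1 by
  construction.
* **MLC1** blocks the (ordered) input — block size `block_size`, default
  ⌈N/10⌉ — greedy-clusters each block at t, selects one representative per
  block-group (`rep_mode`, default almost-central), runs CCBC over the
  representatives, and pools groups whose representatives share a
  component.  The merged cluster's representative is recomputed:
  almost-central over all members while the union holds at most 10·k
  members, over the constituent groups' representatives beyond that
  (bounding the cost at O(k²)).  `block_size = 0` disables blocking: MLC1
  is then plain CCBC and f = 1.
* **MLC** iterates MLC1 over a strictly increasing threshold schedule
  ending at t.  Groups smaller than `s` (default 300) are finalized by MLC1
  at t; larger groups are clustered at the level threshold and their
  subgroups passed on.  Between levels a group is handed over as its member
  sequences with the representative first, preserving the representative as
  the greedy seed.  The default schedule halves the remaining gap to the
  target at each step, stopping once the gap falls below 0.005 and then
  appending the target exactly; an explicit threshold list can be supplied
  instead.  Multi-level refinement only pays when the data have coarse
  structure (groups at low thresholds much larger than at t): on data whose
  between-family similarities sit at a single level, MLC's coarse levels
  find the same groups as MLC1's blocks and save nothing.
* **rMLC** equals MLC for inputs of at most `M` sequences (default 1000).
  Above that, wherever MLC1 would cluster a set larger than M — a block,
  or the representative set of step 2 — the algorithm recurses on that set.
  The recursive schedule starts at the surrounding run's previous level
  threshold when one exists and otherwise stays at the set's target
  threshold; descending further was tried and rejected, because recursing
  through the band of between-group similarities builds mixed coarse
  groups whose single representative misrepresents the minority families
  in them and splits them permanently.  Recursion terminates because every
  recursive call receives a strictly smaller set; a representative set as
  large as the group itself falls back to plain CCBC.

Every algorithm returns a `Partition` (disjoint clusters covering the
input exactly, numbered by first member appearance) for every input,
including N = 0, 1, 2.

## Evaluation

`f_measure` is the clustering F-measure
F(K, C) = (1/n) Σⱼ nʲ · maxᵢ [2 nᵢʲ / (nᵢ + nʲ)]: for each reference class
the best harmonic-mean overlap with any predicted cluster, averaged with
class-size weights.  It is 1 exactly when the partitions agree up to
labels, 0 when they share nothing, and is locked against an independent
brute-force implementation on all partitions of up to six elements in the
test suite.  `optimal_threshold_scan` clusters at every threshold of a grid
(fresh ledger per point, so each f-value reflects a cold-cache run) and
returns the F-measure argmax, ties resolved to the lowest threshold.

## Synthetic data

`generate_families` plants `num_families` families: one common random root,
one ancestor per family derived from it, and members derived from their
ancestor by substitutions at exactly ⌈(1 − within_identity)·L⌉ distinct
positions (each new residue differs from the old).  Ancestor divergence is
calibrated from the target between-family identity b by solving
p² + (1−p)²/(|A|−1) = b for the root-to-ancestor identity p (two ancestors
agree at a position if both kept it or both mutated to the same residue);
this requires b above the random-identity floor 1/|A|.  Optional
single-residue indels (≤ 2% of positions) and a length range (members are
trimmed to a drawn length) add realism; identity-critical tests keep indels
off because aligned identity then equals the planted ungapped identity
exactly.  Everything is reproducible from the integer seed.

What the generator does *not* emulate: substitution-rate heterogeneity,
realistic indel length distributions, phylogenetic correlation inside a
family, chimeras, or the long tail of singleton species in real reference
sets.  Passing the planted-recovery tests therefore shows the algorithms
are correct on separable data, not that any particular real dataset is
separable at a given threshold.

## Problem sizes and study conditions in the tests

The planted-recovery and cost-ordering scenario uses 25 families of 20
sequences (within 0.99, between 0.70, t = 0.95) at lengths 130–160 so the
full-matrix baseline stays cheap to compute, with a *two-tier* structure —
five superfamilies of five families, superfamily roots mutually unrelated —
and a length range so the length-sorted presentation scatters families
across blocks.  The two tiers give MLC the coarse structure multi-level
refinement exploits (a flat single-tier structure provably gives MLC no
advantage over MLC1, see above), mirroring the hierarchical reference data
the method was designed for; MLC and rMLC start their schedules at 0.6,
between the two between-identity tiers.  Under these conditions all five
algorithms recover the planted partition (F = 1) and the comparison counts
order as MLC < MLC1 < N(N−1)/2.

The acceptance script reports, per run: the f-value of CCBC on 100
generated sequences (full-matrix method, cold cache), the F-measure of a
random 50-id, 7-cluster partition evaluated against itself, and the f-value
of MLC1 with blocking disabled on 150 generated sequences after verifying
its partition equals CCBC's.

## Known limitations

* Absolute thresholds are tied to the similarity definition; numbers
  quoted for other aligners or scoring schemes do not transfer.
* MLC/rMLC schedules require some knowledge of the dataset's similarity
  structure; a schedule level falling inside a dense band of between-group
  similarities makes results threshold-sensitive there.
* The greedy first-match rule makes GC (and hence MLC1 block contents)
  dependent on the input ordering; all orderings offered (length, name,
  greedy pre-clustering) are deterministic.
* Comparison counts, not wall time, are the cost model; constant factors
  (alignment length, cache pressure) are outside it.
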