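# Methods

This note documents the models, conventions and numerical choices behind
`colormove`, in the order the pipeline runs.

## Concatenated text and suffix structures

Documents are concatenated in doc-id order into `S`, with one global
terminator `$` (lexicographically smallest) and **no per-document
separators**.  The terminator suffix is attributed to the last document so
that every BWT run has a nonempty color.  Suffixes may cross document
boundaries; the document of a suffix is the document containing its start
position.  Sanitization uppercases sequences and splits on maximal
non-ACGT stretches, keeping the pieces in the same document; because
matching is exact, the spurious adjacencies created by concatenation can
only produce rare short chance matches, which the scoring scheme tolerates.

The suffix array is built by prefix doubling (Manber–Myers) on numpy
`lexsort`, O(n log² n) — a megabase concatenation builds in seconds; the
LCP array uses Kasai's algorithm (numba).  All coordinates are 0-based with
half-open intervals.

## Thresholds

For a run `[s, s+L)` of character `x` and a query character `c ≠ x`, let
`a` be the nearest BWT offset above the run with character `c` and `b` the
nearest below.  The threshold is the within-run offset of the **first
(topmost) minimum** of LCP over `(a, b]`, clamped to `[0, L]`; offsets
strictly below it keep a longer common prefix by repositioning up, the rest
by going down.  With no occurrence above, the threshold is 0 (always
down); with none below, `L` (always up).  The first-minimum tie-break is
fixed for determinism; at a tie either direction preserves the same LCP.

## Move table and repositioning

One row per run stores (character, length, LF destination of the run head
as (run, offset), thresholds, color id).  LF of (i, j) hops to the
destination plus j and fast-forwards across run boundaries.  No
run-splitting/balancing is performed — the constant-time worst case of the
balanced move structure is a performance concern, not a correctness one,
and desk-scale fast-forwards are short.

Repositioning strategies ("effective threshold" decides up vs down at
offset j, up iff `j < threshold`):

- `true` — the stored LCP-derived thresholds;
- `always-up` — threshold = run length (only falls back down when no such
  run exists above);
- `mid-run` — threshold = ⌈L/2⌉ (ceiling chosen; the midpoint convention
  is otherwise arbitrary and only affects odd-length runs by one row).

Up lands on the **last** offset of the nearest preceding run of `c`; down
on the **first** offset of the nearest following run — the nearest offsets
in BWT order, which maximize the retained LCP within the chosen direction.
If the chosen direction has no run of `c`, the other direction is used; a
character absent from the whole BWT yields PML 0 with no LF step and the
tracked position unchanged (the same rule handles non-ACGT read
characters).

## Colors

A run's color is the set of documents of its rows (a set — multiplicity is
discarded).  Colors are deduplicated by first appearance in run order, so
builds are deterministic.  The dense representation is a |D|-bit vector
per color, auto-selected for |D| ≤ 64; beyond that a sparse sorted id
list is used (|C|·b integers, b = mean set bits).  The representation
affects only size accounting, never semantics.

## PML scoring and classification

Scores are tallied on the **post-LF run**, following the pseudocode order
(scores update after the LF step): after LF the tracked row's suffix
begins with the string matched so far, so its run color certifies
documents containing that match up to the run's shared LCP.  Positions
with PML = 0 contribute nothing, including the position immediately after
a repositioning.

Per read: both orientations are queried (references are indexed
forward-only) and the orientation with the higher average PML is kept,
forward winning ties.  The binary gate runs first: a read is considered
in-index only if its average PML strictly exceeds the cutoff.  The cutoff
is the nearest-rank 95th percentile (⌈p/100·n⌉-th smallest) of the average
PMLs of a null-read set — nearest-rank is deterministic and well defined
for small n; at least 20 null reads are required.  The gate can be
disabled when no null set exists.

Multi-class decision: `D_best` is the highest-scoring document, ties to
the smallest doc id; up to `max_secondary` (default 1) further documents
with raw score ≥ 95% of `D_best`'s are co-reported (ties at the top count
against the same budget), and the assigned taxon is `D_best`'s taxon when
reported alone, else the LCA of the reported documents' taxa.  Scores are
raw counts, not normalized — the ratio compares counts over the same set
of read positions, so normalization would cancel.

## Evaluation

At rank ρ, reads whose truth has no ancestor at ρ are excluded.  TP:
prediction's projection to ρ equals the truth's.  VP: prediction strictly
above ρ but on the truth lineage.  FP: everything else classified,
including predictions above ρ that are off the truth lineage.  FN:
unclassified positive reads.  Negative reads (truth `-`) count FP when
classified and are excluded as true negatives when not — the convention of
the Kraken 2 comparisons; `count_negative_fp=False` restricts the tally to
positive reads.  `precision = TP/(TP+FP)`, `recall = TP/(TP+VP+FN+FP)`;
zero denominators yield `None` markers rather than exceptions.

## Synthetic data

The generator emulates a small multi-species bacterial pangenome: a
uniform-random root genome; species ancestors by iid substitution at the
inter-species rate (default 10%); genomes per species at the intra-species
rate (default 1%); one genome per species withheld from the index so
positive reads come from strains the index has not seen, while their
species is represented.  Defaults — 5 species × 3 genomes × 100 kb — give
a ~1 Mb index that exhibits the run/color compression behavior while
building in seconds.

Reads: uniform start, truncated-normal length (default mean 9 kb, sd 3 kb,
min 100 bp, resampled when exceeding the genome), substitutions always to
a different base, single-base insertions and deletions applied
per-position (defaults 3% / 2% / 2%, ≈7% total, ONT-like), half the reads
reverse-complemented.  Null reads descend from a root derived from the
indexed root at 30% substitution divergence (floor 25%), far enough that
homologous matching is no better than chance.

What the simulator does **not** model: structural variation and
rearrangement between genomes, ONT homopolymer error structure and
quality-dependent error rates, compositional bias (GC skew, repeats), and
real taxonomic depth (the generated taxonomy is root → genus → species).
Passing tests therefore demonstrate algorithmic correctness and the
statistical behavior of the gate and scores under an idealized substitution
model, not end-to-end accuracy on real metagenomes.

## Operating characteristics recomputed by `scripts/acceptance.py`

With the default pangenome and 2,000-read sets, the calibrated gate's
empirical type-I error on fresh null reads sits in the binomial band
around 5%, and its power on held-out-strain reads (9 kb mean, 7% error)
saturates near 100%: null averages concentrate well below 1 while positive
averages concentrate near the reciprocal of the combined error + strain
divergence rate.  The script derives every quantity at run time from the
seed it is given; nothing is stored.

## Known limitations

- Naive (unbalanced) move table: adversarial inputs could make fast-forward
  chains long; irrelevant at the supported scales.
- The color table is held uncompressed in memory; meta-color/spanning-tree
  compression schemes are out of scope.
- `true`-threshold queries require thresholds computed at build time;
  thresholdless indexes (mirroring BWT builders that cannot emit
  thresholds) fall back to `mid-run`.
- Quadratic-time test oracles cap cross-validation at texts of a few
  thousand characters; larger sizes are covered by invariants (bijectivity,
  bounds, round trips) rather than exhaustive comparison.
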