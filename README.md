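# colormove

A run-colored move-structure index for multi-class and taxonomic
classification of long sequencing reads against a multi-genome reference
collection (a pangenome or a small reference database).

## The problem and the approach

Taxonomic classifiers must decide, for each read in a metagenomic sample,
which reference genome(s) — or which taxon — it most likely came from.
k-mer indexes are fast but tied to one match length; compressed full-text
indexes find matches of any length but have historically been slow.

`colormove` indexes the forward strand of a concatenated reference
`S = D_0 D_1 … D_{|D|-1} $`, where each *document* `D_i` is a
classification unit (typically all genomes of one species).  It builds on
three ingredients:

- **Move structure.**  The BWT of `S` is stored as its `r` maximal
  equal-letter runs; each run row keeps its character, length, and the
  LF-mapping destination of the run head as a (run, offset) pair, so LF
  steps are table hops plus a short fast-forward.
- **Run colors.**  Each run is annotated with its *color* — the set of
  documents contributing suffixes to its rows.  Distinct colors are
  deduplicated into a color table (`|C| ≤ r`); on repetitive references
  colors are heavily reused and `r/|C|` measures the saving.
- **Pseudo-matching lengths (PML).**  Reads are scanned right to left
  tracking a single BWT offset.  A match extends the current length `ℓ`; a
  mismatch *repositions* to the nearest run of the required character — up
  or down, chosen by per-run thresholds derived from the LCP array (or by
  the threshold-free `mid-run` / `always-up` heuristics) — and resets
  `ℓ = 0`.  `PML[k]` never exceeds the matching statistic `MS[k]`.

Classification tallies, for every read position with `PML > 0`, one count
for each document in the color of the run the PML walk visits.  The
highest-scoring document `D_best` is reported, together with at most one
runner-up scoring ≥ 95% of it; multiple reports resolve to their lowest
common ancestor in the taxonomy.  Before multi-class scoring, a binary gate
discards reads unlikely to be in the index at all: a read is kept only if
its average PML (sum of PMLs over read length, best of both orientations)
exceeds a cutoff calibrated as the 95th percentile of the average PMLs of
*null reads* — a level-0.05 test.

Evaluation follows the Kraken-style per-rank scheme: at rank ρ, a
prediction projecting to the truth's ancestor at ρ is a true positive (TP),
a prediction strictly above ρ but on the truth lineage is a vague positive
(VP), any other classification is a false positive (FP), an unclassified
positive read is a false negative (FN);
`recall = TP/(TP+VP+FN+FP)`, `precision = TP/(TP+FP)`.

A synthetic pangenome/read simulator (documents with controlled inter- and
intra-species divergence, noisy long reads with ground truth, null reads
from a distant clade) makes the whole pipeline testable without downloads.

## Worked example

Two documents `D1 = "ACA"`, `D2 = "ACG"`, read `R = "ACG"`:

```python
import colormove as cm

coll = cm.DocumentCollection(
    [cm.Document(0, "D1", ["ACA"]), cm.Document(1, "D2", ["ACG"])],
    {0: 100, 1: 101})
text  = cm.build_concat(coll)               # S = "ACAACG$"
st    = cm.build_suffix_structures(text)    # BWT = "GC$AAAC"
runs  = cm.find_runs(st.bwt_codes)
table = cm.build_move_table(runs, st, cm.compute_thresholds(runs, st))
colors = cm.build_color_table(cm.compute_run_colors(runs, st), n_docs=2)
cm.assign_colors(table, colors)
res = cm.compute_pmls(table, "ACG", "true")
```

This prints:

```
S = ACAACG$
BWT = GC$AAAC  runs = [('G', 1), ('C', 1), ('$', 1), ('A', 3), ('C', 1)]
colors = [[1], [0], [0, 1]]  run_color_ids = [0, 1, 1, 2, 0]
PML('ACG') = [2, 1, 0]
scores = {0: 2, 1: 2}
r = 5, |C| = 3, r/|C| = 1.67, b = 1.33
```

The BWT has `r = 5` runs; three distinct colors remain after
deduplication (`{D2}`, `{D1}`, `{D1, D2}`).  Scanning `R = "ACG"` right to
left gives `PML = [2, 1, 0]`: the final `G` mismatches the tracked row and
resets to 0, then `C` and `A` extend the match to 1 and 2.  The two
positions with positive PML both land in the run colored `{D1, D2}`, so
both documents score 2 — the read's suffix `AC` genuinely occurs in both.

## Command line

```bash
colormove simulate --out-dir sim --seed 1         # pangenome + reads + truth
colormove build --ref sim/refs.fasta --docmap sim/docmap.tsv \
    --tax sim/taxonomy.tsv --doc2tax sim/doc_taxon.tsv --out sim/index.npz
colormove stats --index sim/index.npz             # r, |C|, r/|C|, b, sizes
colormove calibrate --index sim/index.npz --null-reads sim/null_reads.fastq
colormove classify --index sim/index.npz --reads sim/reads.fastq \
    --null-reads sim/null_reads.fastq --out sim/cls.tsv
colormove evaluate --classifications sim/cls.tsv --truth sim/truth.tsv \
    --tax sim/taxonomy.tsv --ranks species,genus
```

Indexes built with `--no-thresholds` refuse the `true` repositioning
strategy and default to `mid-run`.

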