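# ssphase

Phasing of diploid assembly-graph unitigs from single-cell Strand-seq
alignment evidence.

Modern long-read assemblers (Verkko, hifiasm) produce assembly graphs whose
unitigs still need to be assigned to chromosomes and haplotypes before a
fully phased, telomere-to-telomere assembly can be emitted. Strand-seq — a
single-cell protocol that sequences only the template strand inherited by
each chromosome homolog in each cell — carries a *global* phase signal in the
direction (Watson vs Crick) of read alignments, using only material from the
sample itself, with no parental data required. `ssphase` turns per-library
Strand-seq alignments against the unitigs of a GFA assembly graph into:

* chromosome clusters of unitigs,
* orientation (reverse-complement) corrections per unitig,
* per-cluster phase geometry, and
* per-unitig haplotype marker counts and calls, ready to hand to a
  graph-threading scaffolder (e.g. Rukki) or a k-mer-based trio-mode
  assembler hand-off.

It is aimed at assembly-pipeline developers and genome-assembly
practitioners; everything is callable as a library and as a `ssphase` CLI.
A built-in synthetic Strand-seq generator with planted ground truth makes the
whole engine testable at desk scale.

## Method

For unitig *u* and library *l* with *w* Watson and *c* Crick first-mate
alignments, the **strand state frequency** is

```
SSF(u, l) = (w − c) / (w + c)
```

±1 for a matched (WW/CC) strand state, ≈0 for an unmatched (WC/CW) state.
Each homolog passes W or C to a library independently with probability ½, so
all unitigs of one chromosome share a strand-state pattern: their SSF vectors
over libraries point along a common direction `v_clust`. Clustering uses the
**absolute cosine similarity** |cos θ| between unit-normalized SSF vectors —
absolute, so that misoriented unitigs (negated vectors) still cluster; and
cosine, so that symmetric background from degenerate sequence, which shrinks
every component by the same factor, changes nothing. Unitigs are clustered
in coverage-ranked batches by agglomerative grow / create / merge operations
(merging component-restricted first), then refined (small and sub-2 %-of-
component clusters dissolved, single-cluster components absorbed, one
re-clustering round, refinement repeated).

Misorientation correction clusters each chromosome cluster's vectors *plus a
negated copy of each* with **signed**-cosine average-linkage hierarchical
clustering cut at two clusters; the two sides are the two orientations.

In the phase-informative channel (reads with a single super-maximal exact
match, i.e. unique placements), a diploid cluster's unitig vectors fall on
three directions — haplotype A, haplotype B, homozygous — inside a 2-D
*chromosome plane*. `v_clust` (size-weighted mean of the corrected all-read
vectors) is projected into the plane (first two uncentered principal
directions) and rotated 90°, yielding `v_phase` ∝ (hapA − hapB). Discretized
to {−1, 0, +1}, its non-zero entries mark the phase-informative libraries;
after swapping W/C in the −1 libraries, pooled Watson totals count one
haplotype's markers and Crick totals the other's. Haploid chromosomes (X/Y)
are detected by a PCA variance rule (PC1 > 70 %, PC2 < 20 %), merged, and
given a bisection correction before pooling. Haplotype labels are
arbitrary — parent-of-origin is unknown.

## Worked example

Simulate a small genome (4 autosomes + XY, 64 libraries) and phase it:

```
$ ssphase simulate --n-autosomes 4 --n-libraries 64 --seed 7 --out demo/fix
wrote fixture with 58 unitigs to demo/fix

$ ssphase run --gfa demo/fix/sim.gfa \
    --counts-all demo/fix/counts_all.tsv \
    --counts-phase demo/fix/counts_phase.tsv --out demo/run
[ssphase] graph: components, rDNA tangle, length filter (t+0.0s)
  retained 58 unitigs; removed 0 (0.00% of bp)
[ssphase] strand state: SSF + QC (t+0.0s)
  libraries retained: 58; unitigs retained: 58
[ssphase] chromosome clustering (t+0.0s)
  clusters: 6; unclustered: 0
[ssphase] orientation correction (t+0.0s)
[ssphase] haplotype phasing (t+0.0s)
  calls: {'HAP_A': 25, 'HAP_B': 25, 'HOMOZYGOUS': 8}
```

The 6 clusters are the 4 autosomes plus X and Y (QC dropped 6 libraries
whose strand states were unmatched on almost every chromosome — expected at
this small chromosome count). `demo/run/marker_counts.tsv` holds the
threading-ready table:

```
node       hapA_markers  hapB_markers  call   cluster  flip
chr01_A00  542           13            HAP_A  2        0
chr01_A01  552           20            HAP_A  2        0
...
```

A haplotype-A unitig collects ~2 × depth × (informative libraries) markers
for haplotype A and near zero for B; homozygous unitigs collect a balanced,
larger total. `summary.json` reports the same run machine-readably
(`n_clusters`, `n_haploid_clusters: 2`, call counts, QC drops).

The same pipeline is available in-process:

```python
import ssphase as sp
sim = sp.simulate(sp.SimConfig(seed=1))
result = sp.run_pipeline(sim.graph, sim.counts_all, sim.counts_phase)
result.phasing.markers.head()
```

Real inputs enter through `--mem-dir` (per-library SAM/BAM) and
`--fastmap-dir` (per-library `bwa fastmap` text) in place of the count
tables, or through `ssphase count`. Stage subcommands (`cluster`, `orient`,
`phase`) re-enter the pipeline from intermediate TSVs.

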