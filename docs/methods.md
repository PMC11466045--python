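# Methods

## Model and assumptions

Strand-seq sequences, per cell (library), only the template strand retained
by each chromosome homolog after one BrdU-labeled division. The engine's
statistical model is:

* For each (chromosome, library), each homolog independently inherits
  Watson or Crick with probability ½. A homolog pair is *matched* (WW/CC)
  or *unmatched* (WC/CW), 50/50 in expectation.
* Reads from a homolog align to its template strand. With `w` Watson and
  `c` Crick reads on a unitig in a library, the strand state frequency
  SSF = (w − c)/(w + c) estimates +1/−1 for matched states and 0 for
  unmatched ones. A cell with no reads gets SSF 0 with weight 0 — the
  unique value contributing nothing to cosine similarity.
* All unitigs of one chromosome share the strand-state pattern, so their
  SSF vectors over libraries are parallel; a misoriented unitig's vector is
  negated; degenerate sequence adds symmetric W/C counts that shrink all
  components of the vector by a common factor d/(d+2k) and leave its
  direction unchanged. Absolute cosine similarity is therefore invariant to
  both nuisances, which is why it is the clustering metric.
* In the phase-informative channel (single-SMEM reads only), a unitig
  receives reads only from its own homolog(s). Haplotype-specific vectors
  of a diploid cluster point along two directions whose sum is the
  homozygous direction; all three live in the 2-D chromosome plane spanned
  by `v_clust` and `v_phase ∝ (hapA − hapB)`. Haploid chromosomes have a
  single homolog, hence a 1-D ray in both channels.

The orientation convention (reverse strand = Watson) is arbitrary; a global
relabel negates every SSF vector, and every downstream statistic is
invariant to that (this is tested).

## Pipeline stages and the parameters that matter

All parameters live in one flat `RunConfig` (YAML-serializable); defaults in
parentheses.

* **Graph** — GFA1 S/L lines; segment length from sequence or `LN:i`.
  The bp-largest connected component is treated as the putative acrocentric
  component; the largest connected subgraph of sub-threshold nodes in it
  (the rDNA tangle; measured by summed bp, ties by node count then smallest
  id) is removed with its edges before components are recomputed. A
  "tangle" is any connected subgraph of short nodes — no further shape
  criterion is imposed. Unitigs shorter than `min_unitig_length` (50 000 bp)
  are then dropped; the boundary is inclusive (length ≥ threshold kept).
* **Counting** — all-read channel: first-mate, non-duplicate,
  non-secondary, non-supplementary, properly paired SAM records.
  Phase channel: `bwa fastmap` reads with exactly one SMEM and exactly one
  placement; capped (`*`) hit lists are treated as repetitive and dropped.
* **QC** (`qc.*`) — states discretized at `tau` (0.5) with at least
  `min_cell_count` (5) reads per cell; libraries dropped when more than
  `max_unmatched_frac` (0.8) of their called unitigs are unmatched (failed
  chemistry reads both strands) or when covering fewer than
  `min_unitigs_per_lib` (20) unitigs; unitigs dropped below
  `min_unitig_count` (10) reads. These QC defaults are this package's
  choices: the upstream preprocessing they mirror does not publish its
  values. QC runs once, on the all-read channel; the phase channel inherits
  the retained sets.
* **Clustering** (`cluster.*`) — batches of `batch_size` (1000) unitigs by
  coverage quantile, at least `min_batches` (5) quantiles, processed in
  descending mean coverage so high-signal unitigs seed the clustering.
  Grow/create/merge thresholds all default to 0.6: ideal same-chromosome
  similarity is 1 while cross-chromosome similarity concentrates near
  √(matched-set overlap) ≈ 0.5 under independent inheritance, so 0.6
  separates the two with margin from ~48 libraries up. Unitig–cluster and
  cluster–cluster similarity are mean pairwise |cos| over member vectors;
  argmax ties break lexicographically for determinism. Refinement uses
  `min_cluster_size` (3) and `component_frac` (0.02 of a component's bp).
  Zero-signal unitigs are excluded (cosine undefined) and reported.
* **Orientation** — average linkage on distance 1 − cos over the cluster's
  vectors plus negated copies, cut at 2; the side holding the smallest
  unitig id's original copy is the reference. The global sign per cluster is
  arbitrary and only relative orientation is used downstream. A unitig whose
  original and negated copies land on one side is left unflipped and
  flagged, as are zero-signal unitigs and assignments with within-side mean
  cosine margin below `orientation_low_margin` (0.05).
* **Phasing** (`phase.*`) — PCA is uncentered (SVD of the unit-vector
  matrix): the geometry reasons about directions through the origin, and
  centering would erase the haploid 1-D-ray signature (a `center_pca` flag
  exists for comparison). Haploid rule: PC1 > `pc1_haploid_min` (0.70) and
  PC2 < `pc2_haploid_max` (0.20); flagged clusters are merged, orientation
  correction is re-run on the merged cluster (membership changed), and the
  bisection correction rotates (v_clust, v_phase) so v_clust bisects the
  extremal coordinate-product rays, undoing the size bias of the weighted
  average when the two haploid chromosomes differ in size. `v_phase`
  components with |value| ≥ `vphase_discretize_frac` (0.5) × max|value|
  keep their sign, others are zeroed; relative thresholding is robust to
  library-count scaling. Pooling uses the discretized weights by default
  (`continuous_weights` switches to |v_phase_raw|). The built-in caller —
  a fallback for when no graph-threading tool is run — uses `min_markers`
  (10) and `purity` (0.8); its thresholds are this package's decisions.
  The 90°-rotation direction, and hence which haplotype is "A", is
  arbitrary; negating `v_phase` swaps the labels exactly.

## Synthetic data generator

`simulate(SimConfig)` draws homolog strand states per (chromosome, library),
then Poisson counts: per-homolog mean `allreads_multiplier × depth / 2`
(all-read channel, both homologs) and `depth` per own homolog (phase
channel; homozygous unitigs draw from both, haploid unitigs from their one
homolog). Background adds symmetric Poisson W/C noise at `background_rate`
(low-quality libraries: `low_quality_background`); misoriented unitigs have
W/C swapped in both channels; `leakage_rate` (default 0) models imperfect
uniqueness filtering. Each chromosome is emitted as a simple GFA chain
(hapA – homozygous – hapB), one component per chromosome; X and Y are
separate chains labeled as belonging to different haplotypes.

Defaults are the study conditions used throughout the tests and the
acceptance script: 22 autosomes + XY, 5 unitigs per haplotype, homozygous
fraction 0.2, 96 libraries, phase depth 20, all-read multiplier 2,
background 0.05, misorientation 0.10, unitig lengths uniform on
60 kbp–2 Mbp. The homozygous fraction and length range are this package's
choices of a plausible regime (human assemblies carry a substantial
homozygous unitig fraction; lengths must clear the 50 kbp filter). The
low-quality background default (1.0, i.e. noise comparable to signal) makes
low-quality libraries marginal for the internal caller, so titration
produces a visible quality gradient.

What the generator does *not* emulate: read-level sequences and alignment
artifacts, sparse per-cell coverage of real Strand-seq (every unitig-library
cell is covered here), chimeric/misjoined unitigs, within-unitig strand
switches (inversions), bubble graph topology, and cell-cycle artifacts
beyond the symmetric background. Passing recovery tests on this generator
therefore demonstrates correctness of the estimation geometry, not
robustness to every failure mode of real libraries.

## Numerical choices and degenerate inputs

* Similarities are clipped to [0, 1]; argmax ties break by (unitig id,
  cluster id); all stages are deterministic given inputs and config — there
  is no randomness anywhere in the engine itself, only in the generator.
* Zero SSF vectors are excluded from clustering, left unflipped/flagged in
  orientation, and excluded from PCA.
* Clusters with fewer than two non-zero phase vectors, a singular second
  principal component (haploid-like clusters escaping the variance rule),
  v_clust orthogonal to the plane, or full cancellation of the weighted sum
  are marked unphasable: their unitigs are exported UNASSIGNED rather than
  guessed.
* Bisection correction is skipped with a warning when all coordinate
  products share a sign (a single haploid ray).
* Marker counts are exported as rounded integers; internal math is float.

## Problem sizes

The test suite and acceptance script run the full engine on ~274 unitigs ×
96 libraries (ten seeds, plus 14 titration runs at 192 libraries); one
pipeline run takes well under a second, the whole suite a few seconds. These
sizes exercise every code path at the study's default noise conditions;
scaling to real assemblies (tens of thousands of unitigs) is bounded by the
O(n²) pairwise-similarity cache, which the batch design exists to keep
tractable.

## Known limitations

* Diploid genomes only; higher ploidy would need a different phase geometry.
* Switch errors inside input unitigs are not detected or corrected; a
  chimeric unitig is clustered and called as a whole (low-margin orientation
  assignments are flagged but not split).
* Haplotype calls are HaPU — phased but with unknown parent of origin.
* The fallback caller is intentionally simple; production use should feed
  `marker_counts.tsv` to a graph-threading tool that can exploit topology.
* Library QC assumes the 50/50 matched/unmatched expectation; exotic
  karyotypes (e.g. large runs of homozygosity across many chromosomes)
  would need relaxed thresholds.
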