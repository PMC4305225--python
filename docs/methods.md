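# Methods

## The problem and the approach

Reference-independent binning groups metagenomic fragments by
data-inherent signals rather than by alignment to known genomes. The
signal used here is oligonucleotide composition: the vector of k-mer
frequencies of a fragment is characteristic of its genome of origin.
`sigbin` turns each fragment into such a signature, embeds all
signatures in two dimensions with Barnes-Hut t-SNE, and leaves cluster
delineation to a human (or a script) drawing polygons on the embedding.
The quality of a delineated bin is then quantified with single-copy
essential-gene statistics. The method is deliberately human-in-the-loop:
no automatic cluster detection is provided.

## Signatures

- **k-mer counting.** All overlapping windows of length k consisting
  solely of A/C/G/T are counted; windows containing N or any ambiguity
  code are skipped (not randomized) so counting is deterministic.
  Counting is case-insensitive. A sequence shorter than k yields a zero
  vector flagged by `valid_windows == 0`.
- **Index order** is lexicographic over A<C<G<T. With
  `merge_revcomp=True` each window counts toward the lexicographic
  minimum of {k-mer, reverse complement} and the index keeps the 512
  canonical 5-mers; the default is `False`, preserving the full 4^k
  dimensionality (1,024 at k = 5). Strand-merging is common practice in
  signature-based binning and is exposed as an option.
- **Pseudocount α = 1** is added before normalization. The CLR transform
  requires strictly positive frequencies and short fragments have many
  zero counts; additive smoothing is the simplest deterministic fix. α is
  a tunable (any α > 0); at α = 1 a 1,000-nt fragment's 996 windows are
  shrunk appreciably toward uniform, but identically so for all
  fragments, which leaves relative distances informative.
- **CLR**: clr(x)_i = ln x_i − mean_j ln x_j. Rows sum to zero by
  construction; passing any non-positive frequency raises, which signals
  a missing pseudocount upstream.
- **PCA pre-reduction** to 50 components (configurable, disable with
  `pca_dims=None`) follows standard Barnes-Hut t-SNE practice and makes
  the exact nearest-neighbor search cheap. Implemented as SVD of the
  column-centered matrix with a deterministic sign convention: the
  largest-magnitude loading of each component is made positive.

## Embedding (Barnes-Hut t-SNE)

Written from scratch; the exact O(n²) gradient is retained as an
in-package oracle against which the fast path is tested.

- **Affinities.** Each point keeps its ⌊3·perplexity⌋ exact nearest
  Euclidean neighbors. Neighbor search uses a full distance matrix with
  a stable argsort, so ties break by row index and results are
  reproducible. The per-point precision β_i is bisected (≤ 200
  iterations) until the conditional entropy satisfies
  |log2(perplexity) − H| ≤ 1e-5. If all stored neighbor distances are
  zero (duplicate points) the conditional falls back to uniform.
  When ⌊3·perplexity⌋ exceeds n−1 the neighbor list is truncated to all
  n−1 points (the exact method); perplexity > n−1 is an error because
  the target entropy is then unreachable.
- **Symmetrization**: p_ij = (p_{j|i} + p_{i|j}) / 2n, which sums to 1
  over stored pairs.
- **Gradient.** Attraction is summed over the sparse P with the
  unnormalized Student-t kernel. Repulsion uses a quadtree: leaves hold
  one distinct position with a multiplicity (exact duplicates, and
  points not separated by depth 60, aggregate, so degenerate inputs
  cannot recurse unboundedly); a cell of width w at distance r is
  summarized by its center of mass when w/r < θ. θ = 0 descends to the
  leaves and reproduces the exact sums to machine precision. Each
  point's own self-term is included during traversal and subtracted
  analytically from the partition sum.
- **Optimization** follows the reference recipe: Y ~ Gaussian(0, 1e-4)
  initialization, early exaggeration ×12 for 250 iterations, learning
  rate 200, momentum 0.5 → 0.8 at iteration 250, per-parameter adaptive
  gains (×0.8 on sign agreement, +0.2 otherwise, floored at 0.01),
  re-centering each iteration, 1,000 iterations by default. KL(P‖Q) of
  the *un-exaggerated* P is recorded every 50 iterations. Non-finite
  coordinates abort with a diagnostic; nothing is clipped silently.
- **Reproducibility.** Initialization is keyed to (seed, row index) via
  independent per-row generators, execution is serial, and summation
  orders are fixed, so a run is bit-identical for a fixed seed.
  `n_threads` is recorded in manifests for provenance but does not
  change the execution path: serial execution is what makes the
  bit-reproducibility contract hold, and concurrency is a performance
  concern outside this package's scope. p and q are floored at 1e-12
  inside logarithms only.

## Selection and display

Polygon membership uses the even-odd (ray casting) rule with points
exactly on an edge counted inside; self-intersecting polygons are
permitted and resolved even-odd. This is deterministic and matches the
intuition that a drawn boundary captures the points under it. Display
encodings: point size is min-max-scaled ln(length) into [2, 12] display
units; opacity is min-max-scaled ln(coverage + 1) into [0.2, 1.0] (the
+1 keeps zero-coverage contigs finite); labels map to a categorical
palette; marker-gene carriers render as stars. "Proportional to the
logarithm" fixes only a monotone linear-in-log map; the output ranges
are package conventions.

## Bin assessment

A bin's essential-gene copy numbers are aggregated over its contigs
from a precomputed contig → gene occurrence table. A gene occurring
twice on one contig counts as copy number 2 (per occurrence, not per
contig) — the contamination-sensitive choice. Completeness is
(genes present ≥ once)/|universe|; `single_copy` and `multiple_copies`
partition the present genes. Mbp totals are exact internally and
rounded half-even to two decimals only for display. HMM-based gene
detection is out of scope; the shipped 107-gene universe is a synthetic
stand-in name list (see `_essential_genes_synthetic.py`) whose only
substantive property is its size.

## Synthetic communities

The generator emulates the statistical structure the method assumes:
population-specific composition.

- Each population is an order-4 Markov source (order m configurable);
  order 4 makes 5-mer signatures informative by construction. Transition
  rows are Dirichlet(c,c,c,c) draws with c = 10(1−d)/d for divergence
  d ∈ (0,1] (clamped at 0.05); d = 0 yields exactly uniform rows. Higher
  d → more idiosyncratic composition → more separable populations.
- One genome per population (default 100,000 nt) is simulated and cut
  into fragments at uniform random start positions with lengths
  min + Exponential(mean − min), defaults (1,000, 1,200) nt. Fragments
  may therefore overlap, like redundant assemblies; they are not a
  tiling.
- Coverage is one log-normal draw per population (median 10, σ = 1),
  shared by its fragments — a simple stand-in for per-population
  abundance that gives the opacity channel realistic structure.
- Each marker gene (default: all 107) is planted exactly once per
  genome on a uniformly chosen fragment, making completeness and
  contamination of truth-label bins exact by construction.

**What passing tests on these data do and do not show.** The generator
produces fragments whose within-population composition is homogeneous
and whose between-population divergence is directly controlled. Real
metagenomes add within-genome compositional heterogeneity (rRNA
operons, mobile elements, skew), sequencing and assembly artifacts,
strain-level microdiversity, and uneven fragment-length/coverage
structure — none of which are modeled. Perfect cluster recovery here
demonstrates the pipeline's correctness and sensitivity, not expected
performance on real samples. In particular, at divergence 0.8 the
populations are separable even from ~600-nt fragments, so the
short-fragment regime does not degrade neighbor purity on these data,
whereas on real communities cluster overlap grows as fragments approach
600 nt: that degradation arises when between-population divergence is
comparable to the k-mer sampling noise of short fragments, a regime the
default generator settings deliberately do not occupy.

## Problem sizes and numerical conventions

Automated checks run the full study conditions: communities of 5
populations × 200 fragments (n = 1,000), 1,000 t-SNE iterations,
five seeds at two fragment-length regimes; gradient-oracle comparisons
at n = 300 and calibration checks at n = 500. Key tolerances: perplexity
calibration 1e-5 in entropy bits; Barnes-Hut at θ = 0 vs exact ≤ 1e-9;
frequency/CLR row-sum identities at 1e-9; exact-gradient and KL oracles
at 1e-10. Ties everywhere break by row index; all randomness flows from
explicit integer seeds.

## Known limitations

- O(n²) memory in the neighbor search and KL evaluation bounds
  practical problem sizes at a few tens of thousands of fragments.
- No coverage-aware embedding: coverage is display-only.
- Annotation files are positional (no id column), so they must be
  generated in FASTA order.
- The embedding is not rotation/reflection-canonical; only seeds, not
  geometry, are stable across parameter changes.
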