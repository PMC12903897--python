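# Methods

This note documents the model, the numerical choices, the defaults and
their rationale, and what the synthetic benchmark does and does not
demonstrate.

## Preprocessing

Counts `X` (genes × spots) pass through four deterministic stages:

1. **Gene filter.** Gene *j* is dropped when its zero fraction
   `zex_j = #{spots with zero count}/s` is ≥ τ (default 0.8). The boundary
   case `zex = τ` is removed. The comparison is done on integer zero
   counts against `τ·s`, so the boundary is exact in floating point.
2. **Spot normalization.** Each spot column is divided by its total, so
   spots sum to one. Zero-total spots make this undefined; they are
   rejected with an explicit error, with an opt-in I/O flag to drop them
   instead (a silent drop could mask upstream problems).
3. **HVG selection.** Per-gene variance of the *normalized* matrix with
   population divisor `s` (not `s−1`). The top `m̃` genes (default 2000)
   are kept in their original order; variance ties break toward the
   smaller gene index via a stable sort, making selection deterministic.
4. **Gene scaling.** Each gene row is divided by its maximum, mapping it
   into [0, 1]; all-zero rows are left untouched.

No log transform or size-factor scaling is applied: downstream
factorization operates on the sum-to-one, max-scaled scale directly.

## Adaptive expression-neighbor graph

Expression distances are Euclidean between spot columns of the filtered
normalized matrix (all surviving genes, not just HVGs; a config flag
switches to the HVG matrix for speed on very large slides). Distances are
computed blockwise (`pairwise_distances_chunked`), so the full s × s
matrix is never materialized.

For each spot, the distances to its `k¹max` nearest other spots (self
excluded — the zero self-distance would otherwise absorb all probability)
are sorted ascending as `d̂_1 ≤ … ≤ d̂_{k¹max}`. The connection
probabilities solve

```
min_E Σ_l d̂_l / (1 − E_l)    s.t.   Σ_l E_l = 1 + σ
```

whose stationarity conditions give the closed form
`E_l = (1 − √d̂_l / √ζ)₊` with `√ζ = Σ_l √d̂_l / (k¹max − 1 − σ)`.
The neighbor count per spot is `k_i = #{l : d̂_l < ζ}`; for σ > −1 the
radius always exceeds the nearest distance, so every spot keeps at least
one neighbor. Properties that follow and are verified by tests:
probabilities are non-increasing in distance, lie in [0, 1), and the row
sums to exactly 1 when σ = 0 and the clipped tail is exactly zero.

Degenerate rows with all-zero distances (duplicate spots) have no scale to
adapt to; they fall back to the uniform row with a logged warning.

Two directed rows rarely agree, and the Laplacian quadratic form needs a
symmetric adjacency, so an undirected edge is kept only for **mutual**
pairs (each spot inside the other's selected neighbor set) and weighted by
the mean of the two directed probabilities. Probability rows are not
renormalized after clipping.

σ is a free tuning scalar entering only through `(k¹max − 1 − σ)`.
When set to `"auto"`, a grid (default 0.1 … 0.9) is scanned: for each
value the graph is rebuilt and seeded Louvain (networkx, weighted, default
resolution) counts communities; the chosen σ is the one just before the
sharpest relative increase in community count (> 1.5×, ties toward smaller
σ), falling back to the grid median when no sharp elbow exists. The
selected value is recorded in the run metadata.

`k¹max` has no selection rule; it is an input that should scale with spot
count (default 50, suitable for slides of a few hundred to a few thousand
spots).

## Spatial graph

Binary mutual-kNN on the 2-D coordinates, default `k² = 6` matching the
hexagonal Visium packing; on Visium input the integer array grid
(array_row/array_col) is used by default rather than pixel positions,
because only relative proximity matters and grid units are
platform-stable. Distance ties break toward the smaller spot index, so
regular grids produce a deterministic graph.

Both graphs carry degree matrix `D` (diagonal row sums) and unnormalized
Laplacian `L = D − A`, which is symmetric positive semidefinite with zero
row sums — the identity `Tr(H L Hᵀ) = ½ Σ_{ii′} A_{ii′} ||h_i − h_{i′}||²`
is what makes the penalty pull connected spots together in factor space.

## Factorization

The objective `||X̃ − WH||_F² + α₁Tr(HL¹Hᵀ) + α₂Tr(HL²Hᵀ)` is minimized by
alternating multiplicative updates (W first, then H):

```
W ← W ⊙ (X̃Hᵀ) ⊘ (WHHᵀ + δ)
H ← H ⊙ (WᵀX̃ + α₁HA¹ + α₂HA²) ⊘ (WᵀWH + α₁HD¹ + α₂HD² + δ)
```

* `δ = 1e-12` floors the denominators against 0/0; multiplicative updates
  otherwise never leave the non-negative orthant, and entries that reach
  exactly zero stay zero.
* Graph matrices act sparsely on the right of `H`, keeping one iteration
  at `O(m̃·s·f + nnz·f)`.
* Initialization is i.i.d. uniform(0, 1) from a mandatory integer seed
  (`numpy.random.default_rng`); identical seeds give bit-identical fits.
* Convergence is declared when `errH = max_{pq} |H_t − H_{t−1}|_{pq}`
  drops below ε (default 1e-4); the elementwise max norm was chosen over
  the induced ∞-norm as the stricter and simpler criterion. The iteration
  cap defaults to 500. Both the objective and errH are recorded every
  iteration; the objective trace is non-increasing (verified to 1e-9
  relative tolerance in tests), and with α₁ = α₂ = 0 the trajectory
  coincides with classical Frobenius multiplicative NMF to 1e-10.
* The factor count `f` defaults to the number of domains sought — the
  embedding then gives K-means one axis per expected domain — and can be
  overridden.
* No normalization or identifiability constraint is imposed on the
  columns of `W`; clustering consumes `H` directly, for which scale
  indeterminacy is harmless.

Multiplicative updates converge slowly near a minimum, which matters for
the exact-recovery check: reaching a 1e-3 relative residual on an exact
rank-4 product takes on the order of 10⁴ iterations — the recovery test
and acceptance script budget accordingly, while routine clustering runs
are insensitive to this tail and use the 500-iteration default.

## Clustering, metrics, markers

K-means (Euclidean, 10 seeded restarts, best inertia) on the spot columns
of `H`; labels are renumbered by first appearance so equal seeds give
identical files. ARI uses the chance-adjusted pair-counting form, NMI the
arithmetic normalization `2I/(H+H)` with the `0·log 0 = 0` convention,
purity the majority-class fraction per predicted cluster. All three are
checked against independent brute-force pair-count/contingency oracles.

Marker genes per domain: one-vs-rest Wilcoxon rank-sum (exact enumeration
for small untied groups, tie-corrected normal approximation otherwise, via
`scipy.stats.mannwhitneyu`) on the spot-normalized matrix — the scale on
which between-spot technical variation has been removed. A gene is a
candidate when detected in ≥ 25 % of the domain's spots and
`|log2((mean_in + c)/(mean_out + c))| ≥ 0.25` with pseudocount `c = 1e-9`;
candidates are ranked by |log2FC|. P-values are reported raw; the screen
applies no multiple-testing correction. Domains with fewer than 3 spots
are skipped.

## Defaults

| parameter | default | meaning / rationale |
|---|---|---|
| τ | 0.8 | gene zero-fraction cutoff |
| m̃ | 2000 | HVGs retained |
| k¹max | 50 | expression-neighbor candidates per spot |
| σ | 0.3 (or `auto`) | adaptive-radius residual; 0.3 works well on breast-cancer Visium tissue |
| k² | 6 | hexagonal Visium neighborhood |
| α₁, α₂ | 0.8, 0.1 | expression/spatial penalty weights, the setting validated on breast-cancer tissue |
| f | = K | latent factors |
| ε, max_iter | 1e-4, 500 | convergence threshold / cap |
| K-means restarts | 10 | seeded |

## Synthetic benchmark

The generator emulates the *structure* of sequencing-based spatial data:
spots on an integer grid partitioned into K contiguous domains (stripes,
blocks, or Voronoi cells), domain-specific marker genes (mean
`baseline × effect_size` inside, `baseline` outside, flat background
elsewhere), Poisson or negative-binomial counts (the NB option reflects
the overdispersion of real Visium counts), and independent Bernoulli
dropout producing the zero inflation that the τ filter targets. Defaults:
20×20 grid, 4 stripes, 300 genes, 10 markers per domain, baseline mean
2.0 (a realistic per-gene count for a few-hundred-gene panel), effect
size 5, dropout 0.3, Poisson noise. The same seed yields a bit-identical
dataset, and the generator writes a Visium-style bundle the reader
consumes, so the whole pipeline is testable offline.

What it does **not** emulate: smooth within-domain expression gradients,
spatially correlated noise, cell-type mixtures within spots, library-size
variation between spots, or irregular tissue boundaries. Near-perfect ARI
on this benchmark therefore demonstrates the correctness of the machinery
— graph construction, optimization, clustering — not expected performance
on real tissue, where domain boundaries are weaker and noisier.

## Problem sizes used in tests

Unit tests run on matrices of tens of genes × tens of spots; the
end-to-end and ablation checks use five replicates of the 400-spot
benchmark; descent checks use 50 × 200 instances over 200 iterations; the
recovery check uses 30 × 60 rank-4 products. These sizes keep the full
suite around twenty seconds while exercising every code path at
non-trivial scale.

## Known limitations

* The method is transductive: the factorization embeds the fitted spots
  only, and `transform` returns that embedding rather than projecting new
  spots.
* Exact (blockwise) nearest-neighbor search is used — no approximate-NN
  index — which is fine up to tens of thousands of spots but not beyond.
* The Louvain elbow rule for σ is a heuristic; on graphs whose community
  count varies smoothly it falls back to the grid median.
* No H5-format Visium reader and no histology-image handling.
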