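# spatialnmf

Spatial-domain identification for spatial transcriptomics by **dual
graph-regularized non-negative matrix factorization**.

Spatial transcriptomics platforms (10x Visium, seqFISH, …) measure a
gene-expression profile at every capture location ("spot") of a tissue
slide together with the spot's 2-D position. A central analysis task is to
partition the slide into *spatial domains* — spatially coherent regions
sharing an expression program, such as tumor foci or anatomical layers.
Clustering expression alone ignores spatial context; `spatialnmf` fuses
both modalities inside one factorization.

## Model

Given the preprocessed genes × spots matrix `X̃ ∈ R^{m̃×s}` (filtered,
per-spot sum-to-one normalized, top-variance genes, per-gene max-scaled),
the method solves

```
min_{W≥0, H≥0}  ||X̃ − W H||_F²  +  α₁ Tr(H L¹ Hᵀ)  +  α₂ Tr(H L² Hᵀ)
```

where `W` (m̃ × f) is a gene basis, `H` (f × s) is the spot embedding, and
`L¹`, `L²` are unnormalized graph Laplacians of two spot–spot graphs:

* **A¹ — adaptive expression-neighbor graph.** Each spot receives
  connection probabilities to its `k¹max` nearest expression neighbors from
  the closed-form solution of a constrained neighbor-assignment problem:
  `E_ii′ = (1 − √d_ii′ / √ζ_i)₊` with the adaptive radius
  `√ζ_i = Σ_l √d̂_il / (k¹max − 1 − σ)`, so the *number* of neighbors per
  spot adapts to its local distance profile. Edges are kept only when
  mutual and weighted by the mean of the two directed probabilities. The
  residual parameter σ can be fixed or chosen by a Louvain-elbow grid
  search.
* **A² — spatial mutual-kNN graph.** Binary adjacency between spots that
  list each other among their `k²` spatially nearest neighbors (default 6,
  the hexagonal Visium neighborhood).

The objective is minimized by alternating multiplicative updates that
preserve non-negativity and decrease the objective monotonically; domains
are the K-means clusters of the columns of `H`. Agreement with reference
annotations is scored by ARI, NMI and purity, and per-domain marker genes
are ranked by a one-vs-rest Wilcoxon screen (detection fraction ≥ 25 %,
|log2FC| ≥ 0.25).

## Worked example

Generate a synthetic Visium-style slide (20×20 spot grid, four vertical
stripe domains, 300 genes with domain markers, Poisson counts with 30 %
dropout), run the pipeline, and score against the known labels:

```bash
spatialnmf simulate --out-dir demo_bundle --seed 3
# bundle written to demo_bundle (300 genes × 400 spots, 4 domains)

spatialnmf run --visium-dir demo_bundle \
    --truth-csv demo_bundle/truth_labels.csv \
    --out-dir demo_results --n-domains 4 --seed 3

cat demo_results/metrics.json
# {
#   "ari": 1.0,
#   "nmi": 1.0,
#   "pur": 1.0
# }
```

All four stripe domains are recovered exactly (ARI = NMI = purity = 1.0 on
this seed). `demo_results/` also holds the per-spot labels
(`labels.csv`), the factor embedding (`embedding.csv`), the per-iteration
objective trace, and a `run_metadata.json` that fully reproduces the run
(replaying it yields a byte-identical labels file).

The same pipeline is available as sklearn-style estimators:

```python
from spatialnmf import SpatialDomainIdentifier
from spatialnmf.synthetic import generate_dataset

data = generate_dataset(seed=3)
sdi = SpatialDomainIdentifier(n_domains=4, random_state=3)
labels = sdi.fit_predict(data.counts.values.T, coords=data.coords.coords)
```

Real 10x Visium bundles (Matrix-Market counts + barcodes/features TSV +
`spatial/tissue_positions*.csv`, both dialect variants) are read with
`spatialnmf.io.read_visium`; dense CSV/TSV matrices with
`read_csv_matrix`.

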