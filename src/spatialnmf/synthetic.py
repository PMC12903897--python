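"""Synthetic spatial-transcriptomics data with known domain structure.

Spots sit on an integer grid partitioned into K spatial domains (vertical
stripes, rectangular blocks, or Voronoi cells of random centers).  Each
domain owns a set of marker genes whose mean count is ``effect_size`` times
the baseline inside the domain; all other genes are flat.  Counts are drawn
Poisson or negative-binomial (overdispersed, as Visium counts are), then
thinned by independent Bernoulli dropout — the zero-inflation that the
zero-fraction gene filter targets.

The default configuration — a 20×20 grid with 4 stripe domains, 300 genes,
10 markers per domain at effect size 5, baseline mean 2 and dropout 0.3 —
yields a benchmark that the full pipeline is expected to resolve almost
perfectly, while still exercising sparsity and count noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .datatypes import CountMatrix, DomainAssignment, SpotCoordinates
from .io import write_visium_bundle

LAYOUTS = ("stripes", "blocks", "voronoi")


@dataclass
class SyntheticConfig:
    rows: int = 20
    cols: int = 20
    k: int = 4
    layout: str = "stripes"
    n_genes: int = 300
    n_markers_per_domain: int = 10
    baseline_mean: float = 2.0
    effect_size: float = 5.0
    dropout_rate: float = 0.3
    noise: str = "poisson"  # or "nb"
    nb_dispersion: float = 2.0
    seed: int = 0


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    coords: SpotCoordinates
    truth: DomainAssignment
    params: SyntheticConfig = field(default_factory=SyntheticConfig)

    def write_bundle(self, out_dir) -> None:
        """Emit a Visium-style bundle (plus truth labels CSV) for the reader."""
        out = write_visium_bundle(out_dir, self.counts, self.coords)
        with open(out / "truth_labels.csv", "w") as fh:
            fh.write("spot_id,domain\n")
            for sid, lab in zip(self.counts.spot_ids, self.truth.labels):
                fh.write(f"{sid},{lab}\n")


def _block_shape(k: int) -> tuple[int, int]:
    nr = int(np.floor(np.sqrt(k)))
    while k % nr:
        nr -= 1
    return nr, k // nr


def generate_layout(
    rows: int, cols: int, k: int, layout: str = "stripes", seed: int = 0
) -> tuple[SpotCoordinates, DomainAssignment]:
    """Place spots on a rows × cols grid and assign K domain labels.

    ``stripes``: k vertical bands of near-equal width; ``blocks``: k
    rectangular tiles; ``voronoi``: nearest of k distinct random centers
    (ties toward the smaller center index).
    """
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}")
    if not 2 <= k <= rows * cols:
        raise ValueError(f"require 2 <= k <= rows*cols, got k={k}, grid {rows}x{cols}")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    spot_ids = [f"spot_{int(r)}_{int(c)}" for r, c in coords]

    if layout == "stripes":
        labels = (coords[:, 1] * k // cols).astype(int)
        labels = np.minimum(labels, k - 1)
    elif layout == "blocks":
        nr, nc = _block_shape(k)
        row_band = np.minimum((coords[:, 0] * nr // rows).astype(int), nr - 1)
        col_band = np.minimum((coords[:, 1] * nc // cols).astype(int), nc - 1)
        labels = row_band * nc + col_band
    else:  # voronoi
        rng = np.random.default_rng(seed)
        centers = coords[rng.choice(coords.shape[0], size=k, replace=False)]
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)  # argmin ties resolve to smaller center index

    present = np.unique(labels)
    if present.size < k:
        raise ValueError(
            f"layout produced only {present.size} of {k} domains; use a larger grid"
        )
    # compress to 0..k-1 just in case a block id went unused
    labels = np.searchsorted(present, labels)
    return SpotCoordinates(coords, spot_ids), DomainAssignment(labels=labels, k=k, seed=seed)


def generate_counts(
    truth: DomainAssignment,
    n_genes: int = 300,
    n_markers_per_domain: int = 10,
    baseline_mean: float = 2.0,
    effect_size: float = 5.0,
    dropout_rate: float = 0.3,
    noise: str = "poisson",
    nb_dispersion: float = 2.0,
    seed: int = 0,
) -> CountMatrix:
    """Draw a genes × spots count matrix over a given domain labeling.

    Gene block ``d * n_markers_per_domain : (d+1) * n_markers_per_domain``
    are the markers of domain ``d``; their mean is
    ``baseline_mean * effect_size`` inside the domain and ``baseline_mean``
    outside.  Remaining genes are flat at ``baseline_mean``.
    """
    k = truth.k
    if n_genes < k * n_markers_per_domain:
        raise ValueError(
            f"n_genes={n_genes} < k*n_markers_per_domain={k * n_markers_per_domain}"
        )
    if noise not in ("poisson", "nb"):
        raise ValueError("noise must be 'poisson' or 'nb'")
    if not 0 <= dropout_rate <= 1:
        raise ValueError("dropout_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    s = truth.labels.size
    mean = np.full((n_genes, s), float(baseline_mean))
    for dom in range(k):
        rows = slice(dom * n_markers_per_domain, (dom + 1) * n_markers_per_domain)
        mean[rows, truth.labels == dom] = baseline_mean * effect_size

    if noise == "poisson":
        counts = rng.poisson(mean)
    else:
        theta = float(nb_dispersion)
        counts = rng.negative_binomial(theta, theta / (theta + mean))
    if dropout_rate > 0:
        counts = counts * (rng.random(counts.shape) >= dropout_rate)

    gene_ids = []
    for j in range(n_genes):
        dom = j // n_markers_per_domain if j < k * n_markers_per_domain else None
        gene_ids.append(f"marker_d{dom}_{j}" if dom is not None else f"background_{j}")
    spot_ids = [f"spot_{i}" for i in range(s)]
    return CountMatrix(sp.csr_matrix(counts), gene_ids, spot_ids)


def generate_dataset(config: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate a complete dataset (layout + counts) from one seed."""
    cfg = config or SyntheticConfig()
    if overrides:
        cfg = SyntheticConfig(**{**cfg.__dict__, **overrides})
    coords, truth = generate_layout(cfg.rows, cfg.cols, cfg.k, cfg.layout, cfg.seed)
    counts = generate_counts(
        truth,
        n_genes=cfg.n_genes,
        n_markers_per_domain=cfg.n_markers_per_domain,
        baseline_mean=cfg.baseline_mean,
        effect_size=cfg.effect_size,
        dropout_rate=cfg.dropout_rate,
        noise=cfg.noise,
        nb_dispersion=cfg.nb_dispersion,
        seed=cfg.seed,
    )
    counts = CountMatrix(counts.values, counts.gene_ids, coords.spot_ids)
    return SyntheticDataset(counts=counts, coords=coords, truth=truth, params=cfg)
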