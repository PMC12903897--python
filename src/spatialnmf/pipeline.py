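"""End-to-end spatial-domain identification.

:class:`SpatialDomainIdentifier` chains the full method — preprocessing,
adaptive expression graph (with optional sigma grid search), spatial
mutual-kNN graph, dual graph-regularized NMF, and K-means on the embedding —
as one sklearn-style clusterer.  :func:`run_pipeline` drives the same chain
from a :class:`RunConfig` (file paths in, result files out) for the CLI.

Default hyperparameters follow the settings that work well on Visium-scale
breast-cancer tissue: ``alpha1 = 0.8`` (expression graph), ``alpha2 = 0.1``
(spatial graph), ``sigma = 0.3``, ``k2 = 6`` (the hexagonal Visium
neighborhood), ``tau = 0.8`` and 2000 HVGs.  ``k1_max`` defaults to 50 and
should scale with spot count; the number of factors defaults to the number
of domains sought.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin

from . import graphs as graphs_mod
from .cluster import cluster_embedding, rank_marker_genes
from .datatypes import CountMatrix, SpotCoordinates
from .factorization import fit_factor_model
from .io import read_csv_matrix, read_visium, write_results
from .metrics import score_clustering
from .preprocess import preprocess

logger = logging.getLogger(__name__)


class SpatialDomainIdentifier(ClusterMixin, BaseEstimator):
    """Identify spatial domains from counts + coordinates.

    Parameters mirror the pipeline stages; see the module docstring for the
    rationale behind the defaults.  ``sigma="auto"`` triggers the Louvain
    elbow grid search over ``sigma_grid``.

    Examples
    --------
    >>> from spatialnmf.synthetic import generate_dataset
    >>> data = generate_dataset(seed=0)
    >>> sdi = SpatialDomainIdentifier(n_domains=4, random_state=0)
    >>> labels = sdi.fit_predict(data.counts.values.T, coords=data.coords.coords)
    """

    def __init__(
        self,
        n_domains: int = 4,
        tau: float = 0.8,
        n_top_genes: int = 2000,
        k1_max: int = 50,
        sigma: float | str = 0.3,
        sigma_grid: tuple = graphs_mod.DEFAULT_SIGMA_GRID,
        k2: int = 6,
        alpha1: float = 0.8,
        alpha2: float = 0.1,
        n_factors: int | None = None,
        tol: float = 1e-4,
        max_iter: int = 500,
        n_init: int = 10,
        graph_distance_source: str = "x_filtered",
        random_state: int = 0,
    ):
        self.n_domains = n_domains
        self.tau = tau
        self.n_top_genes = n_top_genes
        self.k1_max = k1_max
        self.sigma = sigma
        self.sigma_grid = sigma_grid
        self.k2 = k2
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.n_factors = n_factors
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.graph_distance_source = graph_distance_source
        self.random_state = random_state

    def fit(self, X, y=None, coords=None):
        """Fit on X (spots × genes counts) and 2-D spot coordinates."""
        if coords is None:
            raise ValueError("coords (n_spots, 2) are required")
        if self.n_domains < 2:
            raise ValueError("n_domains must be >= 2")
        if self.graph_distance_source not in ("x_filtered", "x_hvg"):
            raise ValueError("graph_distance_source must be 'x_filtered' or 'x_hvg'")
        coords = np.asarray(coords, float)
        x = sp.csr_matrix(X).T  # genes × spots
        seed = int(self.random_state)
        timings: dict[str, float] = {}

        t0 = time.perf_counter()
        processed = preprocess(x, tau=self.tau, m_hvg=self.n_top_genes)
        timings["preprocess"] = time.perf_counter() - t0

        dist_source = (
            processed.x_filtered
            if self.graph_distance_source == "x_filtered"
            else processed.x_hvg
        )
        t0 = time.perf_counter()
        if self.sigma == "auto":
            sigma, counts_by_sigma = graphs_mod.select_sigma(
                dist_source, self.k1_max, grid=self.sigma_grid, seed=seed
            )
            logger.info("sigma grid search selected %.3g (communities: %s)", sigma, counts_by_sigma)
        else:
            sigma = float(self.sigma)
        self.sigma_ = sigma
        g1 = graphs_mod.build_expression_graph(dist_source, self.k1_max, sigma)
        timings["expression_graph"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        g2 = graphs_mod.build_spatial_graph(coords, self.k2)
        timings["spatial_graph"] = time.perf_counter() - t0

        f = self.n_factors if self.n_factors is not None else self.n_domains
        t0 = time.perf_counter()
        model = fit_factor_model(
            processed.x_hvg,
            graph1=g1,
            graph2=g2,
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            f=f,
            epsilon=self.tol,
            max_iter=self.max_iter,
            seed=seed,
        )
        timings["factorization"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        assignment = cluster_embedding(model.h, self.n_domains, seed=seed, n_init=self.n_init)
        timings["clustering"] = time.perf_counter() - t0

        self.processed_ = processed
        self.expression_graph_ = g1
        self.spatial_graph_ = g2
        self.model_ = model
        self.assignment_ = assignment
        self.labels_ = assignment.labels
        self.embedding_ = model.h.T
        self.timings_ = timings
        for stage, dt in timings.items():
            logger.info("stage %s: %.2fs", stage, dt)
        return self

    def fit_predict(self, X, y=None, coords=None):
        return self.fit(X, coords=coords).labels_


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    visium_dir: str | None = None
    counts_csv: str | None = None
    coords_csv: str | None = None
    truth_csv: str | None = None
    out_dir: str = "results"
    n_domains: int = 4
    tau: float = 0.8
    m_hvg: int = 2000
    k1_max: int = 50
    sigma: float | str = 0.3
    sigma_grid: tuple = graphs_mod.DEFAULT_SIGMA_GRID
    k2: int = 6
    alpha1: float = 0.8
    alpha2: float = 0.1
    factors: int | None = None
    epsilon: float = 1e-4
    max_iter: int = 500
    seed: int = 0
    graph_distance_source: str = "x_filtered"
    use_pixel_coords: bool = False
    drop_empty_spots: bool = False
    markers: bool = False

    def validate(self) -> None:
        has_visium = self.visium_dir is not None
        has_csv = self.counts_csv is not None and self.coords_csv is not None
        if has_visium == has_csv:
            raise ValueError(
                "exactly one input mode required: --visium-dir OR --counts-csv with --coords-csv"
            )
        if self.n_domains < 2:
            raise ValueError("n_domains must be >= 2")


def _load_inputs(config: RunConfig) -> tuple[CountMatrix, SpotCoordinates]:
    if config.visium_dir is not None:
        return read_visium(
            config.visium_dir,
            use_pixel_coords=config.use_pixel_coords,
            drop_empty_spots=config.drop_empty_spots,
        )
    return read_csv_matrix(
        config.counts_csv, config.coords_csv, drop_empty_spots=config.drop_empty_spots
    )


def _load_truth(path: str, spot_ids: list[str]) -> np.ndarray:
    df = pd.read_csv(path)
    df = df.rename(columns={df.columns[0]: "spot_id", df.columns[1]: "domain"})
    lookup = dict(zip(df["spot_id"].astype(str), df["domain"]))
    missing = [sid for sid in spot_ids if sid not in lookup]
    if missing:
        raise ValueError(f"{len(missing)} spot(s) missing from truth labels, e.g. {missing[:5]}")
    values = [lookup[sid] for sid in spot_ids]
    _, encoded = np.unique(np.asarray(values, dtype=object).astype(str), return_inverse=True)
    return encoded


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute read → preprocess → graphs → factorize → cluster → write.

    Returns the map of written result files.  Raises with the failing stage
    named in the message.
    """
    config.validate()
    stage = "read"
    try:
        counts, coords = _load_inputs(config)
        stage = "fit"
        sdi = SpatialDomainIdentifier(
            n_domains=config.n_domains,
            tau=config.tau,
            n_top_genes=config.m_hvg,
            k1_max=config.k1_max,
            sigma=config.sigma,
            sigma_grid=config.sigma_grid,
            k2=config.k2,
            alpha1=config.alpha1,
            alpha2=config.alpha2,
            n_factors=config.factors,
            tol=config.epsilon,
            max_iter=config.max_iter,
            random_state=config.seed,
        )
        sdi.fit(counts.values.T, coords=coords.coords)

        stage = "score"
        scores = None
        if config.truth_csv is not None:
            truth = _load_truth(config.truth_csv, counts.spot_ids)
            scores = score_clustering(sdi.labels_, truth)

        markers = None
        if config.markers:
            stage = "markers"
            markers = rank_marker_genes(
                sdi.processed_.x_filtered,
                sdi.labels_,
                gene_ids=[counts.gene_ids[i] for i in sdi.processed_.kept_gene_indices],
            )

        stage = "write"
        run_params = asdict(config)
        run_params["sigma_selected"] = sdi.sigma_
        run_params["sigma_grid"] = list(config.sigma_grid)
        return write_results(
            config.out_dir,
            sdi.assignment_,
            sdi.model_,
            counts.spot_ids,
            scores=scores,
            run_params=run_params,
            markers=markers,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def load_config_file(path: str | Path) -> dict:
    """Read a JSON (or simple YAML-ish key: value) config file."""
    text = Path(path).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        out = {}
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line or ":" not in line:
                continue
            key, _, value = line.partition(":")
            out[key.strip()] = json.loads(value.strip()) if value.strip() else None
        return out
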