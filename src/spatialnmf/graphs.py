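"""Spot–spot graph construction.

Two graphs regularize the factorization:

* an **adaptive expression-neighbor graph**: each spot's neighbor count is
  chosen from its own distance profile by a closed-form solution of a
  simplex-constrained problem (clustering-with-adaptive-neighbors style) —
  connection probability ``E = (1 - sqrt(d)/sqrt(zeta))_+`` with the radius
  ``sqrt(zeta) = sum(sqrt(d_hat)) / (k_max - 1 - sigma)`` computed over the
  ``k_max`` nearest candidates; an edge survives only when the relation is
  mutual, and the two directed probabilities are averaged;
* a **spatial mutual-kNN graph**: binary adjacency between spots that list
  each other among their ``k2`` spatially nearest neighbors (default 6, the
  hexagonal Visium neighborhood).

Both are returned with degree and unnormalized Laplacian matrices
``L = D - A`` whose quadratic form ``Tr(H L H^T)`` penalizes embedding
differences between connected spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.metrics import pairwise_distances, pairwise_distances_chunked

from .datatypes import AffinityGraph, SpotCoordinates

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


def expression_distances(x) -> np.ndarray:
    """Pairwise Euclidean distances between spot columns of a genes × spots matrix."""
    x = x.toarray() if sp.issparse(x) else np.asarray(x, float)
    if x.shape[1] < 2:
        raise ValueError("need at least two spots")
    d = pairwise_distances(x.T, metric="euclidean")
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class NeighborProbabilityRow:
    """Adaptive-neighbor solution for one spot.

    ``probs[l]`` is the connection probability to the ``l``-th nearest
    candidate; probabilities are non-increasing in distance and clip to zero
    beyond the adaptive radius ``zeta``.
    """

    distances_sorted: np.ndarray
    neighbor_indices: np.ndarray
    zeta: float
    k_i: int
    probs: np.ndarray


def adaptive_row(
    distances_sorted: np.ndarray,
    sigma: float,
    neighbor_indices: np.ndarray | None = None,
) -> NeighborProbabilityRow:
    """Closed-form adaptive neighbor probabilities for one spot.

    Parameters
    ----------
    distances_sorted
        Ascending distances to the spot's ``k_max`` nearest *other* spots.
    sigma
        Residual parameter of the derivation; must satisfy
        ``k_max - 1 - sigma > 0``.  The grid search of
        :func:`select_sigma` explores 0.1–0.9.

    Notes
    -----
    With ``sqrt(zeta) = sum_l sqrt(d_hat_l) / (k_max - 1 - sigma)``, the
    probability for candidate ``l`` is ``max(0, 1 - sqrt(d_hat_l)/sqrt(zeta))``
    and the selected neighbor count is ``k_i = #{l : d_hat_l < zeta}``,
    clamped to at least one neighbor.  Rows of all-equal distances get the
    uniform solution; rows of all-zero distances (duplicate spots) fall back
    to uniform with a warning, since the radius degenerates.
    """
    d = np.asarray(distances_sorted, dtype=float)
    k_max = d.size
    if k_max < 2:
        raise ValueError("need at least two neighbor candidates")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be sorted ascending")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if k_max - 1 - sigma <= 0:
        raise ValueError(f"require k_max - 1 - sigma > 0, got k_max={k_max}, sigma={sigma}")
    idx = (
        np.arange(k_max) if neighbor_indices is None else np.asarray(neighbor_indices, dtype=int)
    )

    sqrt_d = np.sqrt(d)
    denom = k_max - 1 - sigma
    sqrt_zeta = sqrt_d.sum() / denom
    if sqrt_zeta <= 0:
        # all candidate distances zero: duplicated spots, no scale to adapt to
        logger.warning("all %d neighbor distances are zero; using uniform probabilities", k_max)
        probs = np.full(k_max, 1.0 / k_max)
        return NeighborProbabilityRow(d, idx, 0.0, k_max, probs)

    zeta = sqrt_zeta**2
    probs = np.maximum(0.0, 1.0 - sqrt_d / sqrt_zeta)
    k_i = int(np.count_nonzero(d < zeta))
    if k_i == 0:
        # radius below the nearest distance: keep the single nearest neighbor
        k_i = 1
    return NeighborProbabilityRow(d, idx, float(zeta), k_i, probs)


def _knn_from_distance_rows(d_row: np.ndarray, row_offset: int, k: int) -> np.ndarray:
    """Per-row indices of the k nearest other spots, ties toward smaller index."""
    n_rows, s = d_row.shape
    out = np.empty((n_rows, k), dtype=int)
    for r in range(n_rows):
        row = d_row[r].copy()
        row[row_offset + r] = np.inf  # exclude self
        order = np.argsort(row, kind="stable")[:k]
        out[r] = order
    return out


def _neighbor_candidates(x_spots: np.ndarray, k: int, working_memory: float | None = None):
    """Blockwise exact kNN: yields (row indices, neighbor indices, distances)."""
    start = 0
    for chunk in pairwise_distances_chunked(
        x_spots, metric="euclidean", working_memory=working_memory
    ):
        nbrs = _knn_from_distance_rows(chunk, start, k)
        dists = np.take_along_axis(chunk, nbrs, axis=1)
        yield np.arange(start, start + chunk.shape[0]), nbrs, dists
        start += chunk.shape[0]


def laplacian(adjacency: sp.spmatrix) -> tuple[sp.spmatrix, sp.spmatrix]:
    """Degree matrix (diagonal row sums) and unnormalized Laplacian ``L = D - A``."""
    a = sp.csr_matrix(adjacency)
    if (abs(a - a.T) > 1e-12 * max(1.0, abs(a).max() if a.nnz else 1.0)).nnz:
        raise ValueError("adjacency must be symmetric")
    deg = np.asarray(a.sum(axis=1)).ravel()
    d = sp.diags(deg, format="csr")
    return d, (d - a).tocsr()


def _finalize_graph(adjacency: sp.spmatrix, kind: str) -> AffinityGraph:
    a = sp.csr_matrix(adjacency)
    a.setdiag(0)
    a.eliminate_zeros()
    a = (a + a.T) * 0.5  # enforce exact symmetry against float noise
    d, lap = laplacian(a)
    return AffinityGraph(adjacency=a, degrees=d, laplacian=lap, kind=kind)


def build_expression_graph(
    x, k1_max: int, sigma: float, working_memory: float | None = None
) -> AffinityGraph:
    """Adaptive expression-neighbor graph over spot columns of ``x``.

    Each spot solves :func:`adaptive_row` over its ``k1_max`` nearest other
    spots; an (i, i′) edge exists only when each spot lies in the other's
    selected neighbor set, weighted by the mean of the two directed
    probabilities.
    """
    x = x.toarray() if sp.issparse(x) else np.asarray(x, float)
    s = x.shape[1]
    if not 2 <= k1_max < s:
        raise ValueError(f"require 2 <= k1_max < n_spots, got k1_max={k1_max}, n_spots={s}")

    rows_i, cols_i, vals = [], [], []
    selected = []  # (i, j) directed membership pairs
    for row_ids, nbrs, dists in _neighbor_candidates(x.T, k1_max, working_memory):
        for r, i in enumerate(row_ids):
            sol = adaptive_row(dists[r], sigma, nbrs[r])
            in_set = np.zeros(k1_max, dtype=bool)
            in_set[: sol.k_i] = True
            selected.append((i, nbrs[r][in_set]))
            rows_i.append(np.full(k1_max, i))
            cols_i.append(nbrs[r])
            vals.append(sol.probs)

    directed_probs = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(s, s),
    )
    member_rows = np.concatenate([np.full(len(js), i) for i, js in selected])
    member_cols = np.concatenate([js for _, js in selected])
    membership = sp.csr_matrix(
        (np.ones(member_rows.size, dtype=bool), (member_rows, member_cols)), shape=(s, s)
    )
    mutual = membership.multiply(membership.T)
    a = directed_probs.multiply(mutual)
    a = (a + a.T) * 0.5
    return _finalize_graph(a, "expression")


def build_spatial_graph(coords: SpotCoordinates | np.ndarray, k2: int = 6) -> AffinityGraph:
    """Binary mutual-kNN graph on 2-D spot coordinates.

    Distance ties are broken toward the smaller spot index, so the neighbor
    sets — and hence the graph — are deterministic even on regular grids.
    """
    xy = coords.coords if isinstance(coords, SpotCoordinates) else np.asarray(coords, float)
    s = xy.shape[0]
    if not 1 <= k2 < s:
        raise ValueError(f"require 1 <= k2 < n_spots, got k2={k2}, n_spots={s}")
    rows, cols = [], []
    for row_ids, nbrs, _dists in _neighbor_candidates(xy, k2):
        rows.append(np.repeat(row_ids, k2))
        cols.append(nbrs.ravel())
    membership = sp.csr_matrix(
        (np.ones(s * k2, dtype=bool), (np.concatenate(rows), np.concatenate(cols))),
        shape=(s, s),
    )
    mutual = membership.multiply(membership.T)
    a = sp.csr_matrix(mutual, dtype=float)
    return _finalize_graph(a, "spatial")


def louvain_community_count(graph: AffinityGraph, seed: int, resolution: float = 1.0) -> int:
    """Number of Louvain communities of the weighted adjacency (seeded)."""
    g = nx.from_scipy_sparse_array(graph.adjacency)
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed, resolution=resolution)
    return len(comms)


def select_sigma(
    x,
    k1_max: int,
    grid=DEFAULT_SIGMA_GRID,
    seed: int = 0,
) -> tuple[float, dict[float, int]]:
    """Pick sigma by the elbow of the Louvain community count.

    For each grid value the expression graph is rebuilt and Louvain run at
    default resolution with a fixed seed; the chosen sigma is the one just
    before the sharpest (> 1.5×) relative increase in community count, ties
    toward smaller sigma.  If no jump exceeds 1.5×, the grid median is
    returned.  Returns (sigma, {sigma: community count}).
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("sigma grid is empty")
    counts: dict[float, int] = {}
    for sig in grid:
        graph = build_expression_graph(x, k1_max, sig)
        if graph.adjacency.nnz == 0:
            logger.warning("sigma=%.3g yields an edgeless graph; skipped", sig)
            continue
        counts[sig] = louvain_community_count(graph, seed=seed)
    usable = sorted(counts)
    if len(usable) < 2:
        if not usable:
            raise ValueError("no sigma in the grid produced a usable graph")
        return usable[0], counts
    ratios = [counts[usable[t + 1]] / max(counts[usable[t]], 1) for t in range(len(usable) - 1)]
    best = int(np.argmax(ratios))  # argmax keeps the first (smallest sigma) on ties
    if ratios[best] > 1.5:
        return usable[best], counts
    # no sharp elbow: fall back to the median grid value (lower middle on ties)
    return usable[(len(usable) - 1) // 2], counts
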