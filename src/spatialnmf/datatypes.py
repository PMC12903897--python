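"""Lightweight containers for the pipeline's intermediate products.

Matrices follow the field convention for spatial transcriptomics: genes are
rows, spots (capture locations) are columns.  The sklearn-style estimators in
:mod:`spatialnmf.factorization` and :mod:`spatialnmf.pipeline` present the
transposed (spots × genes) view instead, matching the samples × features
convention; these containers are the functional API's currency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp


class FormatError(ValueError):
    """A required input file is missing or malformed."""


class AlignmentError(ValueError):
    """Spot identifiers of two inputs cannot be reconciled."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
        raise ValueError(f"duplicate {what}: {dupes}")
    return ids


@dataclass
class CountMatrix:
    """Raw expression counts, genes × spots, with identifiers.

    ``values`` is kept sparse (CSR); densification happens only inside
    operations that need dense arithmetic.
    """

    values: sp.spmatrix
    gene_ids: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.spot_ids = _check_unique(self.spot_ids, "spot ids")
        m, s = self.values.shape
        if m != len(self.gene_ids) or s != len(self.spot_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes / {len(self.spot_ids)} spots"
            )
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise ValueError("counts contain non-finite entries")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]


@dataclass
class SpotCoordinates:
    """2-D spot positions, one row per spot, aligned with ``spot_ids``."""

    coords: np.ndarray
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (n_spots, 2), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        self.spot_ids = _check_unique(self.spot_ids, "spot ids")
        if len(self.spot_ids) != self.coords.shape[0]:
            raise ValueError("spot_ids length does not match coords")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]


@dataclass
class DomainAssignment:
    """Per-spot integer domain labels in ``{0, ..., k-1}``."""

    labels: np.ndarray
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError(f"labels outside {{0,...,{self.k - 1}}}")


@dataclass
class ClusteringScores:
    """External agreement scores between predicted and true domains."""

    ari: float
    nmi: float
    pur: float

    def as_dict(self) -> dict[str, float]:
        return {"ari": float(self.ari), "nmi": float(self.nmi), "pur": float(self.pur)}


@dataclass
class FactorModel:
    """Fitted non-negative factorization X̃ ≈ W H.

    ``w`` is the gene basis (m̃ × f); ``h`` is the spot embedding (f × s) that
    downstream clustering consumes.
    """

    w: np.ndarray
    h: np.ndarray
    objective_trace: np.ndarray
    err_trace: np.ndarray
    iterations: int
    converged: bool
    seed: int
    alpha1: float
    alpha2: float
    epsilon: float
    max_iter: int

    @property
    def n_factors(self) -> int:
        return self.w.shape[1]

    def metadata(self) -> dict:
        return {
            "factors": int(self.n_factors),
            "alpha1": float(self.alpha1),
            "alpha2": float(self.alpha2),
            "epsilon": float(self.epsilon),
            "max_iter": int(self.max_iter),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "seed": int(self.seed),
        }


@dataclass
class AffinityGraph:
    """Symmetric spot–spot adjacency with degree and Laplacian matrices.

    ``kind`` is ``"expression"`` (adaptive neighbor probabilities, weighted)
    or ``"spatial"`` (mutual-kNN, binary).
    """

    adjacency: sp.spmatrix
    degrees: sp.spmatrix
    laplacian: sp.spmatrix
    kind: str = "expression"

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2
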