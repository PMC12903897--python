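"""Count preprocessing: gene filtering, per-spot normalization, highly
variable gene (HVG) selection, and per-gene max scaling.

The functional API works on genes × spots matrices (sparse or dense).
:class:`ExpressionPreprocessor` exposes the same chain as an sklearn
transformer on the spots × genes orientation.

The four stages, applied in order:

1. drop gene *j* when its zero fraction ``zex_j = #{spots with zero} / s``
   is ≥ ``tau`` (default 0.8);
2. divide each spot column by its total so every spot sums to one;
3. keep the ``m_hvg`` genes with the largest population variance
   (divisor ``s``) of the normalized values, in original gene order;
4. divide each gene row by its maximum, mapping every gene into [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import CountMatrix

logger = logging.getLogger(__name__)


def _as_matrix(x) -> sp.csr_matrix | np.ndarray:
    if isinstance(x, CountMatrix):
        return x.values
    if sp.issparse(x):
        return sp.csr_matrix(x)
    return np.asarray(x, dtype=float)


def filter_genes(counts, tau: float = 0.8) -> tuple[sp.csr_matrix, np.ndarray]:
    """Remove genes whose zero-expression fraction is ≥ ``tau``.

    Returns the surviving genes × spots matrix (order preserved) and the
    indices of kept genes in the original gene list.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    x = _as_matrix(counts)
    x = sp.csr_matrix(x) if not sp.issparse(x) else x
    s = x.shape[1]
    # integer zero counts against tau*s: the zex >= tau boundary stays exact
    zero_counts = s - x.getnnz(axis=1)
    kept = np.flatnonzero(zero_counts < tau * s)
    if kept.size == 0:
        raise ValueError(
            f"all {x.shape[0]} genes have zero fraction >= tau={tau}; "
            "increase tau or check the input"
        )
    return x[kept], kept


def normalize_spots(x) -> sp.csr_matrix:
    """Scale each spot column to sum to one.

    Columns with zero totals are rejected; the I/O layer offers a flag to
    drop such spots before they reach this stage.
    """
    x = _as_matrix(x)
    x = sp.csr_matrix(x)
    totals = np.asarray(x.sum(axis=0)).ravel()
    if (totals <= 0).any():
        bad = int((totals <= 0).sum())
        raise ValueError(f"{bad} spot(s) have zero total expression")
    return x @ sp.diags(1.0 / totals)


def gene_variances(x) -> np.ndarray:
    """Per-gene population variance across spots (divisor ``s``)."""
    x = _as_matrix(x)
    if sp.issparse(x):
        mean = np.asarray(x.mean(axis=1)).ravel()
        mean_sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    else:
        mean = x.mean(axis=1)
        mean_sq = (x**2).mean(axis=1)
    return mean_sq - mean**2


def select_hvg(x, m_hvg: int = 2000) -> tuple[sp.csr_matrix, np.ndarray]:
    """Keep the ``m_hvg`` most variable genes, preserving gene order.

    Variance ties are broken toward the smaller gene index (stable sort).
    If fewer genes exist than requested, all are kept with a warning.
    """
    if m_hvg < 1:
        raise ValueError(f"m_hvg must be >= 1, got {m_hvg}")
    x = _as_matrix(x)
    x = sp.csr_matrix(x)
    m = x.shape[0]
    if m <= m_hvg:
        if m < m_hvg:
            logger.warning("only %d genes available for %d requested HVGs; keeping all", m, m_hvg)
        return x, np.arange(m)
    var = gene_variances(x)
    # stable sort on -variance: equal variances resolve to the earlier index
    top = np.sort(np.argsort(-var, kind="stable")[:m_hvg])
    return x[top], top


def scale_genes(x) -> np.ndarray:
    """Divide each gene row by its maximum; all-zero rows stay zero.

    Returns a dense array: this is the last stage and the factorization
    consumes it densely.
    """
    x = _as_matrix(x)
    x = np.asarray(x.todense()) if sp.issparse(x) else x.copy()
    if x.size and x.min() < 0:
        raise ValueError("scale_genes expects non-negative input")
    row_max = x.max(axis=1)
    nz = row_max > 0
    x[nz] = x[nz] / row_max[nz, None]
    return x


@dataclass
class ProcessedMatrix:
    """Filtered/normalized matrix X′ and the HVG-standardized matrix X̃."""

    x_filtered: sp.csr_matrix  # m′ × s, spot columns sum to 1
    x_hvg: np.ndarray  # m̃ × s, entries in [0, 1]
    kept_gene_indices: np.ndarray  # filter survivors, into the original list
    hvg_gene_indices: np.ndarray  # HVGs, into the original list
    tau: float
    m_hvg: int


def preprocess(counts, tau: float = 0.8, m_hvg: int = 2000) -> ProcessedMatrix:
    """Run the full chain filter → normalize → HVG-select → scale."""
    filtered, kept = filter_genes(counts, tau)
    x_prime = normalize_spots(filtered)
    x_sel, hvg_local = select_hvg(x_prime, m_hvg)
    x_tilde = scale_genes(x_sel)
    return ProcessedMatrix(
        x_filtered=x_prime,
        x_hvg=x_tilde,
        kept_gene_indices=kept,
        hvg_gene_indices=kept[hvg_local],
        tau=tau,
        m_hvg=m_hvg,
    )


class ExpressionPreprocessor(TransformerMixin, BaseEstimator):
    """Sklearn view of the preprocessing chain (X: spots × genes).

    ``transform`` returns the HVG-standardized matrix (spots × m̃).  Gene
    selection is decided on the data passed to ``fit``; like other
    feature-selecting transformers the same gene subset is then applied to
    new data.

    Parameters
    ----------
    tau : float, default 0.8
        Zero-fraction threshold above which (≥) a gene is discarded.
    n_top_genes : int, default 2000
        Number of highly variable genes retained.
    """

    def __init__(self, tau: float = 0.8, n_top_genes: int = 2000):
        self.tau = tau
        self.n_top_genes = n_top_genes

    def fit(self, X, y=None):
        result = preprocess(sp.csr_matrix(X).T, tau=self.tau, m_hvg=self.n_top_genes)
        self.kept_gene_indices_ = result.kept_gene_indices
        self.hvg_gene_indices_ = result.hvg_gene_indices
        self.n_features_in_ = sp.csr_matrix(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        x = normalize_spots_subset(
            sp.csr_matrix(X).T, self.hvg_gene_indices_, self.kept_gene_indices_
        )
        return scale_genes(x).T

    def fit_transform(self, X, y=None, **fit_params):
        result = preprocess(sp.csr_matrix(X).T, tau=self.tau, m_hvg=self.n_top_genes)
        self.kept_gene_indices_ = result.kept_gene_indices
        self.hvg_gene_indices_ = result.hvg_gene_indices
        self.n_features_in_ = sp.csr_matrix(X).shape[1]
        return result.x_hvg.T


def normalize_spots_subset(
    x_raw: sp.csr_matrix, hvg_indices: np.ndarray, kept_indices: np.ndarray
) -> sp.csr_matrix:
    """Normalize spots over the filtered gene set, then restrict to HVGs.

    Spot totals are computed on the filter-surviving genes (as in the fitted
    chain), not on the HVG subset alone.
    """
    filtered = x_raw[kept_indices]
    x_prime = normalize_spots(filtered)
    local = np.searchsorted(kept_indices, hvg_indices)
    return x_prime[local]
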