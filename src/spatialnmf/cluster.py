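"""Domain assignment from the factor embedding, and marker-gene screening.

Spatial domains are the K-means clusters of the spot embedding H; marker
genes per domain come from a one-vs-rest Wilcoxon rank-sum screen with an
expression-fraction filter and a log2 fold-change threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans

from .datatypes import DomainAssignment

logger = logging.getLogger(__name__)

#: pseudocount guarding zero means in the fold-change ratio
LFC_PSEUDOCOUNT = 1e-9


def relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Map labels to 0..k-1 in order of first appearance (determinism aid)."""
    labels = np.asarray(labels)
    mapping: dict = {}
    out = np.empty_like(labels, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_embedding(h: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> DomainAssignment:
    """K-means over the spot columns of the f × s embedding H.

    Runs ``n_init`` seeded restarts and keeps the best inertia; output
    labels are renumbered by first appearance so identical seeds give
    identical assignments.
    """
    h = np.asarray(h, float)
    s = h.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > s:
        raise ValueError(f"k={k} exceeds the number of spots {s}")
    points = h.T
    n_distinct = np.unique(points, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct embedding columns")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(points)
    return DomainAssignment(labels=relabel_first_appearance(raw), k=k, seed=seed)


def rank_marker_genes(
    x_norm,
    labels,
    gene_ids: list[str] | None = None,
    min_frac: float = 0.25,
    min_abs_lfc: float = 0.25,
    top_n: int = 20,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker screen per domain.

    For each domain, a gene is a candidate when it is detected (count > 0)
    in at least ``min_frac`` of the domain's spots and
    ``|log2((mean_in + c) / (mean_out + c))| >= min_abs_lfc`` with
    pseudocount ``c = 1e-9``.  Candidates are ranked by ``|log2FC|``
    descending; the ``top_n`` per domain are returned as a tidy frame with
    columns (domain, gene, log2fc, pvalue, rank).  Domains with fewer than
    3 spots are skipped with a warning.  P-values are raw (no
    multiple-testing correction is applied by the screen).
    """
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must be in [0, 1]")
    x = x_norm.toarray() if sp.issparse(x_norm) else np.asarray(x_norm, float)
    labels = np.asarray(labels).ravel()
    if x.shape[1] != labels.size:
        raise ValueError("labels length must equal the number of spots")
    domains = np.unique(labels)
    if domains.size < 2:
        raise ValueError("marker screening needs at least 2 domains")
    m = x.shape[0]
    names = gene_ids if gene_ids is not None else [f"gene_{j}" for j in range(m)]

    records = []
    for dom in domains:
        inside = labels == dom
        if inside.sum() < 3:
            logger.warning("domain %s has %d spots; marker screen skipped", dom, inside.sum())
            continue
        x_in, x_out = x[:, inside], x[:, ~inside]
        frac = (x_in > 0).mean(axis=1)
        lfc = np.log2(
            (x_in.mean(axis=1) + LFC_PSEUDOCOUNT) / (x_out.mean(axis=1) + LFC_PSEUDOCOUNT)
        )
        candidates = np.flatnonzero((frac >= min_frac) & (np.abs(lfc) >= min_abs_lfc))
        order = candidates[np.argsort(-np.abs(lfc[candidates]), kind="stable")][:top_n]
        for rank, j in enumerate(order, start=1):
            stat_res = mannwhitneyu(x_in[j], x_out[j], alternative="two-sided", method="auto")
            records.append(
                {
                    "domain": dom,
                    "gene": names[j],
                    "log2fc": float(lfc[j]),
                    "pvalue": float(stat_res.pvalue),
                    "rank": rank,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["domain", "gene", "log2fc", "pvalue", "rank"]
    )
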