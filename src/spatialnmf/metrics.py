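"""External clustering-agreement metrics: ARI, NMI, purity.

ARI is the chance-adjusted pair-counting Rand index; NMI uses the
arithmetic normalization ``2 I(pred, truth) / (H(pred) + H(truth))``;
purity is the fraction of spots falling in their cluster's majority truth
class.  All three are invariant to relabeling of either argument.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .datatypes import ClusteringScores


def _check_pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"label length mismatch: {pred.size} vs {truth.size}")
    if pred.size < 2:
        raise ValueError("need at least two samples")
    return pred, truth


def adjusted_rand_index(pred, truth) -> float:
    """ARI = (RI - E[RI]) / (max RI - E[RI]); 1 means perfect agreement."""
    pred, truth = _check_pair(pred, truth)
    return float(adjusted_rand_score(truth, pred))


def normalized_mutual_information(pred, truth) -> float:
    """NMI with arithmetic normalization; 0 when either labeling is constant."""
    pred, truth = _check_pair(pred, truth)
    return float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))


def purity(pred, truth) -> float:
    """Mean over spots of membership in the cluster's majority truth class."""
    pred, truth = _check_pair(pred, truth)
    table = contingency_matrix(truth, pred)
    return float(table.max(axis=0).sum() / pred.size)


def score_clustering(pred, truth) -> ClusteringScores:
    """All three agreement scores in one container."""
    return ClusteringScores(
        ari=adjusted_rand_index(pred, truth),
        nmi=normalized_mutual_information(pred, truth),
        pur=purity(pred, truth),
    )
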