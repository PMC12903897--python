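"""Dual graph-regularized NMF solved by multiplicative updates.

The objective, for a standardized genes × spots matrix ``X̃`` and the two
spot graphs with Laplacians ``L1`` (expression) and ``L2`` (spatial):

    min_{W>=0, H>=0}  ||X̃ - W H||_F^2
                      + alpha1 * Tr(H L1 H^T) + alpha2 * Tr(H L2 H^T)

with gene basis ``W`` (m̃ × f) and spot embedding ``H`` (f × s).  The
alternating multiplicative updates

    W <- W ⊙ (X̃ H^T) ⊘ (W H H^T)
    H <- H ⊙ (W^T X̃ + alpha1 H A1 + alpha2 H A2)
           ⊘ (W^T W H + alpha1 H D1 + alpha2 H D2)

keep both factors non-negative and monotonically decrease the objective;
with ``alpha1 = alpha2 = 0`` they reduce exactly to the classical
Frobenius-norm multiplicative NMF rules.  Iteration stops when the
elementwise max change of ``H`` falls below ``epsilon``.

:class:`GraphRegularizedNMF` wraps these updates as an sklearn transformer
(X: spots × genes; transform yields the spots × f embedding).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import AffinityGraph, FactorModel

#: additive floor applied to update denominators to avoid 0/0
DENOM_FLOOR = 1e-12


def _dense(x) -> np.ndarray:
    return x.toarray() if sp.issparse(x) else np.asarray(x, float)


def objective(x_hvg, w, h, l1=None, l2=None, alpha1: float = 0.0, alpha2: float = 0.0) -> float:
    """Evaluate the regularized objective at (W, H)."""
    x = _dense(x_hvg)
    if w.shape[0] != x.shape[0] or h.shape[1] != x.shape[1] or w.shape[1] != h.shape[0]:
        raise ValueError(
            f"shape mismatch: X {x.shape}, W {w.shape}, H {h.shape}"
        )
    val = float(np.linalg.norm(x - w @ h, "fro") ** 2)
    if alpha1 and l1 is not None:
        val += alpha1 * float(np.sum((h @ l1) * h))  # Tr(H L H^T)
    if alpha2 and l2 is not None:
        val += alpha2 * float(np.sum((h @ l2) * h))
    return val


def update_w(x_hvg, w, h) -> np.ndarray:
    """One multiplicative step on the gene basis W."""
    x = _dense(x_hvg)
    numer = x @ h.T
    denom = w @ (h @ h.T) + DENOM_FLOOR
    return w * (numer / denom)


def update_h(x_hvg, w, h, a1=None, a2=None, d1=None, d2=None,
             alpha1: float = 0.0, alpha2: float = 0.0) -> np.ndarray:
    """One multiplicative step on the spot embedding H.

    The graph adjacency/degree matrices act sparsely on the right of H, so
    a step costs O(m̃·s·f + nnz·f).
    """
    x = _dense(x_hvg)
    numer = w.T @ x
    denom = (w.T @ w) @ h
    if alpha1 and a1 is not None:
        numer = numer + alpha1 * (h @ a1)
        denom = denom + alpha1 * (h @ d1)
    if alpha2 and a2 is not None:
        numer = numer + alpha2 * (h @ a2)
        denom = denom + alpha2 * (h @ d2)
    return h * (numer / (denom + DENOM_FLOOR))


def fit_factor_model(
    x_hvg,
    graph1: AffinityGraph | None = None,
    graph2: AffinityGraph | None = None,
    alpha1: float = 0.0,
    alpha2: float = 0.0,
    f: int = 10,
    epsilon: float = 1e-4,
    max_iter: int = 500,
    seed: int = 0,
) -> FactorModel:
    """Run the alternating updates from a seeded uniform(0,1) initialization.

    Stops when ``errH = max|H_t - H_{t-1}|`` drops below ``epsilon`` or at
    ``max_iter``.  Both the objective and errH are recorded per iteration.
    """
    if f < 1:
        raise ValueError(f"f must be >= 1, got {f}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    x = _dense(x_hvg)
    m, s = x.shape
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.0, 1.0, size=(m, f))
    h = rng.uniform(0.0, 1.0, size=(f, s))

    a1 = d1 = l1 = a2 = d2 = l2 = None
    if graph1 is not None and alpha1:
        a1, d1, l1 = graph1.adjacency, graph1.degrees, graph1.laplacian
    if graph2 is not None and alpha2:
        a2, d2, l2 = graph2.adjacency, graph2.degrees, graph2.laplacian

    obj_trace, err_trace = [], []
    converged = False
    t = 0
    for t in range(1, max_iter + 1):
        w = update_w(x, w, h)
        h_new = update_h(x, w, h, a1, a2, d1, d2, alpha1, alpha2)
        err = float(np.max(np.abs(h_new - h))) if h_new.size else 0.0
        h = h_new
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(h))):
            raise FloatingPointError(f"non-finite factor entries at iteration {t}")
        obj_trace.append(objective(x, w, h, l1, l2, alpha1, alpha2))
        err_trace.append(err)
        if err < epsilon:
            converged = True
            break

    return FactorModel(
        w=w,
        h=h,
        objective_trace=np.asarray(obj_trace),
        err_trace=np.asarray(err_trace),
        iterations=t,
        converged=converged,
        seed=seed,
        alpha1=alpha1,
        alpha2=alpha2,
        epsilon=epsilon,
        max_iter=max_iter,
    )


class GraphRegularizedNMF(TransformerMixin, BaseEstimator):
    """Dual graph-regularized NMF as an sklearn transformer.

    Parameters
    ----------
    n_components : int, default 10
        Number of latent factors f.
    alpha1, alpha2 : float, default 0
        Weights of the expression-graph and spatial-graph Laplacian
        penalties on the embedding.
    tol : float, default 1e-4
        Convergence threshold on the elementwise max change of the
        embedding between iterations.
    max_iter : int, default 500
        Iteration cap.
    random_state : int or RandomState, default 0
        Seeds the uniform(0,1) factor initialization.

    The graphs are data-dependent, so they are passed to ``fit`` rather
    than the constructor::

        model = GraphRegularizedNMF(n_components=4, alpha1=0.8, alpha2=0.1)
        embedding = model.fit_transform(X, expression_graph=g1, spatial_graph=g2)

    Attributes
    ----------
    components_ : ndarray (n_components, n_genes)
        Gene basis (the transpose of W above).
    embedding_ : ndarray (n_spots, n_components)
        Spot embedding (the transpose of H above).
    objective_trace_, err_trace_ : ndarray
        Per-iteration objective value and embedding change.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_components: int = 10,
        alpha1: float = 0.0,
        alpha2: float = 0.0,
        tol: float = 1e-4,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None, expression_graph=None, spatial_graph=None):
        self.fit_transform(X, expression_graph=expression_graph, spatial_graph=spatial_graph)
        return self

    def fit_transform(self, X, y=None, expression_graph=None, spatial_graph=None):
        x = _dense(X).T  # to genes × spots
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else 0
        model = fit_factor_model(
            x,
            graph1=expression_graph,
            graph2=spatial_graph,
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            f=self.n_components,
            epsilon=self.tol,
            max_iter=self.max_iter,
            seed=seed,
        )
        self.model_ = model
        self.components_ = model.w.T
        self.embedding_ = model.h.T
        self.objective_trace_ = model.objective_trace
        self.err_trace_ = model.err_trace
        self.n_iter_ = model.iterations
        self.converged_ = model.converged
        self.n_features_in_ = x.shape[0]
        return self.embedding_

    def transform(self, X):
        """Embedding of the fitted data (the model is transductive)."""
        check_is_fitted(self)
        return self.embedding_
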