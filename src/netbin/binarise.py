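"""Binarisation strategies for weighted connectivity networks.

Five strategies convert a symmetric weight matrix into a simple 0/1 graph:

* proportional threshold — keep a fixed fraction of the strongest edges;
* MST — the maximum-total-weight spanning tree (n-1 edges, density 2/n);
* USP — union of shortest paths on log-transformed distances;
* CST — the proportional threshold whose global clustering coefficient
  (transitivity) is closest to 0.5, balancing open and closed triples;
* ECO — keep the strongest round(1.5 n) edges (density ~ 3/(n-1)).

Each strategy is exposed both as a scikit-learn style stateless transformer
operating on stacks of weight matrices, and as a module-level function
returning a :class:`~netbin.core.BinaryNetwork`.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, List

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree
from sklearn.base import BaseEstimator, TransformerMixin

from .core import (
    BinaryNetwork,
    DistanceMatrix,
    WeightedNetwork,
    as_weight_matrix,
    n_pairs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "proportional_threshold",
    "mst",
    "usp",
    "cst",
    "eco",
    "distance_transform",
    "log_distance_matrix",
    "ProportionalThreshold",
    "MaximumSpanningTree",
    "UnionOfShortestPaths",
    "ClusterSpanThreshold",
    "EfficiencyCostThreshold",
    "make_binarizer",
]


# ---------------------------------------------------------------------------
# edge ordering and top-k selection


def _sorted_pairs(W: np.ndarray):
    """Upper-triangle pairs sorted by (weight desc, i asc, j asc).

    The lexicographic tail makes cutoff ties reproducible.
    """
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def _top_k_adjacency(W: np.ndarray, k: int) -> np.ndarray:
    n = W.shape[0]
    i, j, _ = _sorted_pairs(W)
    A = np.zeros((n, n), dtype=np.uint8)
    A[i[:k], j[:k]] = 1
    return A | A.T


def proportional_threshold(W, fraction: float) -> BinaryNetwork:
    """Keep the k = round(fraction * n(n-1)/2) strongest edges.

    Ties at the cutoff are broken by a stable (weight desc, i asc, j asc)
    order, so the result is reproducible for equal weights.
    """
    Wm = as_weight_matrix(W)
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    k = int(round(fraction * n_pairs(Wm.shape[0])))
    A = _top_k_adjacency(Wm, k)
    return BinaryNetwork(A, method="PROP", params={"fraction": fraction, "k": k})


# ---------------------------------------------------------------------------
# maximum-weight spanning tree


def mst(W) -> BinaryNetwork:
    """Maximum-total-weight spanning tree: n-1 edges, density 2/n.

    Computed as the minimum spanning tree of the negated weights.  The
    input must be connected as a weighted graph (all-positive weights on a
    complete matrix suffice).
    """
    Wm = as_weight_matrix(W)
    n = Wm.shape[0]
    if not np.any(Wm):
        raise ValueError("cannot build a spanning tree of an all-zero weight matrix")
    T = minimum_spanning_tree(sparse.csr_matrix(-Wm))
    A = (T.toarray() != 0).astype(np.uint8)
    A = A | A.T
    m = int(A.sum()) // 2
    if m != n - 1:
        raise ValueError(
            f"weighted graph is disconnected: spanning forest has {m} edges, expected {n - 1}"
        )
    return BinaryNetwork(A, method="MST")


# ---------------------------------------------------------------------------
# log-distance transform and union of shortest paths


def distance_transform(W) -> DistanceMatrix:
    """Map weights to distances: d_ij = -ln(w_ij) / alpha.

    alpha is the smallest positive integer for which every off-diagonal
    distance is strictly below 1.  All off-diagonal weights must lie
    strictly in (0, 1); use :func:`log_distance_matrix` for automatic
    rescaling of out-of-range inputs.
    """
    Wm = as_weight_matrix(W)
    n = Wm.shape[0]
    off = ~np.eye(n, dtype=bool)
    w = Wm[off]
    if np.any(w <= 0.0):
        raise ValueError("distance transform undefined: zero off-diagonal weight (infinite distance)")
    if np.any(w >= 1.0):
        raise ValueError("distance transform requires off-diagonal weights strictly below 1")
    neglog = -np.log(Wm, out=np.zeros_like(Wm), where=off)
    max_nl = neglog[off].max()
    alpha = 1
    while max_nl / alpha >= 1.0:  # smallest N with max(-ln w)/N < 1
        alpha += 1
    D = neglog / alpha
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(distances=D, alpha=alpha)


def log_distance_matrix(W, rescale_eps: float = 1e-6) -> DistanceMatrix:
    """Distance transform with domain repair for out-of-range weights.

    If any off-diagonal weight falls outside (0, 1) — routine for WCH
    networks with s > 0 — the weights are first linearly rescaled to
    (eps, 1 - eps).  Rescaling is monotone, so edge ranking is unchanged.
    """
    Wm = as_weight_matrix(W)
    n = Wm.shape[0]
    off = ~np.eye(n, dtype=bool)
    w = Wm[off]
    if np.any(w <= 0.0) or np.any(w >= 1.0):
        lo, hi = w.min(), w.max()
        if hi == lo:
            Wr = np.full_like(Wm, 0.5)
        else:
            Wr = rescale_eps + (Wm - lo) * (1.0 - 2.0 * rescale_eps) / (hi - lo)
        np.fill_diagonal(Wr, 0.0)
        logger.info(
            "weights outside (0,1) [min=%g, max=%g]; linearly rescaled to (%g, %g) before log transform",
            lo, hi, rescale_eps, 1.0 - rescale_eps,
        )
        return distance_transform(Wr)
    return distance_transform(Wm)


def usp(W, all_paths: bool = False, rescale_eps: float = 1e-6) -> BinaryNetwork:
    """Union of shortest paths on the log-transformed distance matrix.

    One shortest path per unordered node pair is taken from per-source
    Dijkstra predecessor trees (deterministic tie-breaking); the returned
    edge set is the union of their edges, so the graph is connected and
    spans all nodes.  With ``all_paths=True`` the union runs over every
    shortest path (an edge is kept if it lies on any tight path).
    """
    dist = log_distance_matrix(W, rescale_eps=rescale_eps)
    D = dist.distances
    n = D.shape[0]
    dmat, pred = dijkstra(D, directed=False, return_predecessors=True)
    A = np.zeros((n, n), dtype=np.uint8)
    if all_paths:
        tol = 1e-12
        iu, ju = np.triu_indices(n, k=1)
        for u, v in zip(iu, ju):
            # edge (u,v) lies on a shortest i->j path iff the triangle is tight
            through = dmat[:, u][:, None] + D[u, v] + dmat[v, :][None, :]
            if np.any(through <= dmat + tol):
                A[u, v] = 1
    else:
        # every predecessor-tree edge (pred[i,j], j) lies on the i->j path
        targets = np.tile(np.arange(n), n)
        sources = pred.ravel()
        ok = sources >= 0
        A[sources[ok], targets[ok]] = 1
    A = A | A.T
    return BinaryNetwork(A, method="USP", params={"alpha": dist.alpha, "all_paths": all_paths})


# ---------------------------------------------------------------------------
# cluster-span threshold


def _cst_scan(W: np.ndarray, lo: int = 15, hi: int = 85):
    """Transitivity of the strongest-k network at each scanned density.

    Returns (ks, transitivities) for k = round(i/100 * pairs), i = lo..hi,
    duplicates collapsed.  Triangle and triple counts are maintained
    incrementally while edges are inserted in decreasing-weight order.
    """
    n = W.shape[0]
    P = n_pairs(n)
    ks = sorted({int(round(i / 100.0 * P)) for i in range(lo, hi + 1)})
    i_idx, j_idx, _ = _sorted_pairs(W)

    adj = np.zeros((n, n), dtype=bool)
    deg = np.zeros(n, dtype=np.int64)
    tri3 = 0  # 3 * triangle count grows by 3*|N(u) & N(v)| per edge
    triples = 0  # sum over nodes of C(deg, 2)
    trans = []
    checkpoints = iter(ks)
    next_k = next(checkpoints)
    k_max = ks[-1]
    for e in range(k_max + 1):
        while e == next_k:
            trans.append(tri3 / triples if triples > 0 else np.nan)
            try:
                next_k = next(checkpoints)
            except StopIteration:
                next_k = -1
        if e == k_max:
            break
        u, v = i_idx[e], j_idx[e]
        tri3 += 3 * int(np.count_nonzero(adj[u] & adj[v]))
        triples += int(deg[u] + deg[v])
        adj[u, v] = adj[v, u] = True
        deg[u] += 1
        deg[v] += 1
    return np.array(ks), np.array(trans)


def cst(W, lo: int = 15, hi: int = 85) -> BinaryNetwork:
    """Cluster-span threshold.

    Scans proportional thresholds at integer density percentages lo..hi,
    computes the global clustering coefficient (transitivity, 3 x triangles
    / connected triples) of each, and returns the network whose
    transitivity is closest to 0.5 — the point where open and closed
    triples balance.  Ties break toward the lower density.
    """
    Wm = as_weight_matrix(W)
    n = Wm.shape[0]
    if n < 4:
        raise ValueError("cluster-span threshold needs n >= 4")
    ks, trans = _cst_scan(Wm, lo, hi)
    dev = np.abs(trans - 0.5)
    if np.all(np.isnan(dev)):
        raise ValueError("no scanned density yields a defined transitivity")
    best = int(np.nanargmin(dev))  # first minimum -> lower density on ties
    k = int(ks[best])
    A = _top_k_adjacency(Wm, k)
    return BinaryNetwork(
        A,
        method="CST",
        params={"k": k, "transitivity": float(trans[best]), "scan_lo": lo, "scan_hi": hi},
    )


# ---------------------------------------------------------------------------
# efficiency-cost optimisation threshold


def eco(W) -> BinaryNetwork:
    """ECO threshold: keep the strongest round(1.5 n) edges.

    Approximates the density maximising (local + global efficiency)/cost,
    giving density ~ 3/(n-1).  For tiny networks where 1.5 n exceeds the
    number of pairs, the complete graph is returned with a warning.
    """
    Wm = as_weight_matrix(W)
    n = Wm.shape[0]
    if n < 3:
        raise ValueError("ECO threshold needs n >= 3")
    k = int(round(1.5 * n))
    P = n_pairs(n)
    if k > P:
        warnings.warn(
            f"round(1.5n) = {k} exceeds the {P} available pairs; returning the complete graph",
            stacklevel=2,
        )
        k = P
    A = _top_k_adjacency(Wm, k)
    return BinaryNetwork(A, method="ECO", params={"k": k})


# ---------------------------------------------------------------------------
# scikit-learn style transformers


def _iter_matrices(X) -> List[np.ndarray]:
    if isinstance(X, (WeightedNetwork, np.ndarray)) and getattr(X, "ndim", 2) == 2:
        X = [X]
    elif isinstance(X, np.ndarray) and X.ndim == 3:
        X = list(X)
    return [as_weight_matrix(W) for W in X]


class BaseBinarizer(BaseEstimator, TransformerMixin):
    """Stateless transformer turning weight-matrix stacks into 0/1 stacks.

    ``X`` may be a single (n, n) matrix, a (batch, n, n) array, or an
    iterable of matrices / :class:`WeightedNetwork`.  ``transform`` returns
    a (batch, n, n) uint8 array; ``binarise`` returns the provenance-
    carrying :class:`BinaryNetwork` for one input.
    """

    method: str = "BASE"

    def binarise(self, W) -> BinaryNetwork:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y=None):
        mats = _iter_matrices(X)
        self.n_nodes_ = mats[0].shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack([self.binarise(W).adjacency for W in _iter_matrices(X)])

    def densities(self, X) -> np.ndarray:
        """Realised edge density of each binarised input."""
        return np.array([self.binarise(W).density for W in _iter_matrices(X)])


class ProportionalThreshold(BaseBinarizer):
    method = "PROP"

    def __init__(self, fraction: float = 0.4):
        self.fraction = fraction

    def binarise(self, W) -> BinaryNetwork:
        return proportional_threshold(W, self.fraction)


class MaximumSpanningTree(BaseBinarizer):
    method = "MST"

    def binarise(self, W) -> BinaryNetwork:
        return mst(W)


class UnionOfShortestPaths(BaseBinarizer):
    method = "USP"

    def __init__(self, all_paths: bool = False, rescale_eps: float = 1e-6):
        self.all_paths = all_paths
        self.rescale_eps = rescale_eps

    def binarise(self, W) -> BinaryNetwork:
        return usp(W, all_paths=self.all_paths, rescale_eps=self.rescale_eps)


class ClusterSpanThreshold(BaseBinarizer):
    method = "CST"

    def __init__(self, lo: int = 15, hi: int = 85):
        self.lo = lo
        self.hi = hi

    def binarise(self, W) -> BinaryNetwork:
        return cst(W, lo=self.lo, hi=self.hi)


class EfficiencyCostThreshold(BaseBinarizer):
    method = "ECO"

    def binarise(self, W) -> BinaryNetwork:
        return eco(W)


def make_binarizer(tag: str) -> BaseBinarizer:
    """Build a binarizer from a method tag.

    Recognised tags: ``CST``, ``MST``, ``USP``, ``ECO`` and ``PROP:<frac>``
    (e.g. ``PROP:0.4``); bare ``PROP`` defaults to fraction 0.4.
    """
    t = tag.upper()
    if t == "CST":
        return ClusterSpanThreshold()
    if t == "MST":
        return MaximumSpanningTree()
    if t == "USP":
        return UnionOfShortestPaths()
    if t == "ECO":
        return EfficiencyCostThreshold()
    if t.startswith("PROP"):
        frac = float(t.split(":", 1)[1]) if ":" in t else 0.4
        return ProportionalThreshold(fraction=frac)
    raise ValueError(f"unknown binarisation method tag: {tag!r}")
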