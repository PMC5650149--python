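"""Graph metrics and the per-method metric triples.

Ten metrics cover three topological categories — segregation, efficiency
and irregularity.  Each network type is summarised by the three metrics
appropriate to its construction::

    CST      (P,   L,   V)      MST   (LF,  D,   MD)
    USP      (C,   P,   V)      ECO   (C,   L,   V)
    PROP     (C,   L,   V)      WEIGHTED (C_W, Eff, mu_W)

where P = edge density, L = characteristic path length, V = degree
variance, C = mean local clustering, LF = leaf fraction, D = diameter,
MD = maximum degree, C_W = weighted (Onnela) clustering, Eff = efficiency
and mu_W = mean edge weight.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, shortest_path

from .binarise import log_distance_matrix
from .core import BinaryNetwork, MetricTriple, WeightedNetwork, as_weight_matrix, n_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "char_path_length",
    "efficiency",
    "diameter",
    "clustering_mean_local",
    "transitivity",
    "weighted_clustering",
    "leaf_fraction",
    "edge_density",
    "degree_variance",
    "max_degree",
    "mean_weight",
    "metric_triple",
    "METHOD_TRIPLES",
]

METHOD_TRIPLES = {
    "CST": ("P", "L", "V"),
    "MST": ("LF", "D", "MD"),
    "USP": ("C", "P", "V"),
    "ECO": ("C", "L", "V"),
    "PROP": ("C", "L", "V"),
    "WEIGHTED": ("C_W", "Eff", "mu_W"),
}


def _as_adjacency(A) -> np.ndarray:
    if isinstance(A, BinaryNetwork):
        return A.adjacency
    M = np.asarray(A)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {M.shape}")
    if not np.array_equal(M, M.astype(bool)):
        raise ValueError("adjacency entries must be 0/1")
    return M.astype(np.uint8)


def _binary_distances(A: np.ndarray) -> np.ndarray:
    return shortest_path(sparse.csr_matrix(A), method="D", directed=False, unweighted=True)


def char_path_length(A, on_disconnected: str = "exclude-pairs") -> float:
    """Characteristic path length L: mean shortest-path length over pairs.

    Disconnected pairs (infinite distance) are excluded from the average
    with a logged warning; with ``on_disconnected="largest-component"``
    the average is instead taken inside the largest connected component.
    """
    A = _as_adjacency(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("characteristic path length needs n >= 2")
    if on_disconnected == "largest-component":
        ncomp, labels = connected_components(sparse.csr_matrix(A), directed=False)
        if ncomp > 1:
            keep = labels == np.bincount(labels).argmax()
            A = A[np.ix_(keep, keep)]
            n = A.shape[0]
            if n < 2:
                raise ValueError("largest component has fewer than 2 nodes")
    d = _binary_distances(A)
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no connected node pairs: path length undefined")
    if not finite.all():
        logger.warning(
            "graph is disconnected: %d of %d ordered pairs excluded from L",
            int((~finite).sum()), vals.size,
        )
    return float(vals[finite].mean())


def efficiency(N, distances: str = "inverse") -> float:
    """Efficiency: mean over ordered pairs of 1/d(i, j), with 1/inf = 0.

    Binary inputs use hop distances.  Weighted inputs use the canonical
    inverse lengths d = 1/w by default; ``distances="log"`` switches to
    the log-transformed distances used by the shortest-path union (which
    become degenerate when the strongest weight approaches 1).
    """
    if isinstance(N, BinaryNetwork):
        M = N.adjacency
        weighted = False
    else:
        M = np.asarray(N.weights if isinstance(N, WeightedNetwork) else N, dtype=float)
        weighted = not np.array_equal(M, M.astype(bool))
    n = M.shape[0]
    if n < 2:
        raise ValueError("efficiency needs n >= 2")
    if weighted:
        if distances == "log":
            D = log_distance_matrix(M).distances
        elif distances == "inverse":
            with np.errstate(divide="ignore"):
                D = np.where(M > 0, 1.0 / np.where(M > 0, M, 1.0), np.inf)
            np.fill_diagonal(D, 0.0)
        else:
            raise ValueError(f"unknown distances mode {distances!r}")
        d = shortest_path(D, method="D", directed=False)
    else:
        d = _binary_distances(M.astype(np.uint8))
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def diameter(A) -> float:
    """Largest shortest-path length; errors on disconnected input."""
    A = _as_adjacency(A)
    ncomp, _ = connected_components(sparse.csr_matrix(A), directed=False)
    if ncomp > 1:
        raise ValueError(f"diameter undefined: graph has {ncomp} connected components")
    d = _binary_distances(A)
    return float(d.max())


def _triangle_counts(A: np.ndarray) -> np.ndarray:
    Af = A.astype(float)
    return np.diag(Af @ Af @ Af) / 2.0


def clustering_mean_local(A) -> float:
    """Watts-Strogatz mean local clustering; degree < 2 nodes contribute 0."""
    A = _as_adjacency(A)
    if A.shape[0] < 3:
        raise ValueError("local clustering needs n >= 3")
    deg = A.sum(axis=1).astype(float)
    tri = _triangle_counts(A)
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def transitivity(A) -> float:
    """Global clustering coefficient: 3 x triangles / connected triples."""
    A = _as_adjacency(A)
    deg = A.sum(axis=1).astype(float)
    triples = float((deg * (deg - 1)).sum()) / 2.0
    if triples == 0:
        raise ValueError("transitivity undefined: no connected triples")
    tri = _triangle_counts(A).sum() / 3.0
    return float(3.0 * tri / triples)


def weighted_clustering(W) -> float:
    """Onnela weighted clustering coefficient, averaged over nodes.

    Per node, the geometric mean of triangle edge weights is summed over
    neighbour pairs and normalised by k(k-1).  Weights above 1 are first
    rescaled by the maximum (with a warning); weights already in [0, 1]
    are used as-is, so binary matrices reduce exactly to the unweighted
    local clustering.
    """
    Wm = as_weight_matrix(W)
    if Wm.shape[0] < 3:
        raise ValueError("weighted clustering needs n >= 3")
    wmax = Wm.max()
    if wmax > 1.0:
        warnings.warn("weights exceed 1; rescaling by the maximum before clustering", stacklevel=2)
        Wm = Wm / wmax
    M = np.cbrt(Wm)
    num = np.diag(M @ M @ M)  # = 2 * sum over neighbour pairs of geometric means
    k = (Wm > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, num / denom, 0.0)
    return float(c.mean())


def leaf_fraction(A) -> float:
    """Fraction of degree-1 nodes (the leaves of a tree)."""
    A = _as_adjacency(A)
    deg = A.sum(axis=1)
    return float((deg == 1).sum() / A.shape[0])


def edge_density(A) -> float:
    """P = 2m / n(n-1)."""
    A = _as_adjacency(A)
    n = A.shape[0]
    return float(int(A.sum()) // 2 / n_pairs(n)) if n > 1 else 0.0


def degree_variance(A) -> float:
    """Population variance (divide by n) of the degree sequence."""
    A = _as_adjacency(A)
    if A.shape[0] < 2:
        raise ValueError("degree variance needs n >= 2")
    return float(np.var(A.sum(axis=1)))


def max_degree(A) -> int:
    A = _as_adjacency(A)
    return int(A.sum(axis=1).max())


def mean_weight(W) -> float:
    """Mean of the off-diagonal upper-triangle weights (mu_W)."""
    Wm = as_weight_matrix(W)
    iu = np.triu_indices(Wm.shape[0], k=1)
    return float(Wm[iu].mean())


_BINARY_FNS = {
    "P": edge_density,
    "L": char_path_length,
    "V": degree_variance,
    "C": clustering_mean_local,
    "LF": leaf_fraction,
    "D": diameter,
    "MD": max_degree,
}
_WEIGHTED_FNS = {"C_W": weighted_clustering, "Eff": efficiency, "mu_W": mean_weight}


def metric_triple(network, method: str) -> MetricTriple:
    """Compute the (M1, M2, M3) triple for a network of the given type.

    ``method`` is one of CST, MST, USP, ECO, PROP (binary input) or
    WEIGHTED (weight-matrix input).
    """
    tag = method.upper().split(":", 1)[0]
    if tag not in METHOD_TRIPLES:
        raise ValueError(f"unknown method tag {method!r}")
    names = METHOD_TRIPLES[tag]
    fns = _WEIGHTED_FNS if tag == "WEIGHTED" else _BINARY_FNS
    values = tuple(float(fns[name](network)) for name in names)
    return MetricTriple(method=tag, names=names, values=values)
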