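"""Core containers for weighted and binary connectivity networks.

The universal currency of the package is a symmetric, nonnegative weight
matrix with a zero diagonal (:class:`WeightedNetwork`).  Binarisation
strategies turn it into a :class:`BinaryNetwork`, which remembers the
method that produced it and its realised edge density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "WeightedNetwork",
    "BinaryNetwork",
    "DistanceMatrix",
    "MetricTriple",
    "as_weight_matrix",
    "validate_weight_matrix",
    "n_pairs",
    "child_rng",
]


def n_pairs(n: int) -> int:
    """Number of unordered node pairs, n(n-1)/2."""
    return n * (n - 1) // 2


def child_rng(master_seed, *key: int) -> np.random.Generator:
    """Deterministic, order-independent child generator.

    Children are derived from the master entropy via a spawn key, so the
    i-th member of a bank is the same no matter how many siblings were
    drawn before it.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def validate_weight_matrix(W: np.ndarray, *, atol: float = 1e-10) -> np.ndarray:
    """Validate and return a symmetric nonnegative zero-diagonal matrix."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if W.shape[0] < 2:
        raise ValueError("network needs at least 2 nodes")
    if not np.all(np.isfinite(W)):
        raise ValueError("weight matrix contains non-finite entries")
    if not np.allclose(W, W.T, atol=atol):
        raise ValueError("weight matrix is not symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("weight matrix diagonal must be zero")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    return W


def as_weight_matrix(W) -> np.ndarray:
    """Accept a WeightedNetwork or a raw array; return the validated matrix."""
    if isinstance(W, WeightedNetwork):
        return W.weights
    return validate_weight_matrix(W)


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative weight matrix with zero diagonal.

    Parameters
    ----------
    weights
        (n, n) symmetric matrix, w_ij >= 0, w_ii = 0.
    node_labels
        Optional list of n node identifiers, preserved by file round-trips.
    """

    weights: np.ndarray
    node_labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.weights = validate_weight_matrix(self.weights)
        if self.node_labels is not None:
            self.node_labels = list(self.node_labels)
            if len(self.node_labels) != self.n:
                raise ValueError("node_labels length does not match matrix size")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryNetwork:
    """Simple undirected 0/1 graph with method provenance.

    ``density`` is exactly 2m/(n(n-1)) for the realised edge count m.
    """

    adjacency: np.ndarray
    method: str = "PROP"
    params: dict = field(default_factory=dict)
    density: float = field(init=False)

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if not np.array_equal(A, A.astype(bool)):
            raise ValueError("adjacency entries must be 0/1")
        A = A.astype(np.uint8)
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency is not symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = A
        self.density = self.n_edges / n_pairs(self.n) if self.n > 1 else 0.0

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class DistanceMatrix:
    """Log-transformed distances d_ij = -ln(w_ij)/alpha, all in (0, 1)."""

    distances: np.ndarray
    alpha: int


@dataclass
class MetricTriple:
    """The three metric values prescribed for a given network type."""

    method: str
    names: tuple
    values: tuple

    @property
    def m1(self) -> float:
        return self.values[0]

    @property
    def m2(self) -> float:
        return self.values[1]

    @property
    def m3(self) -> float:
        return self.values[2]
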