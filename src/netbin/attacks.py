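"""Size-preserving random and targeted topological attacks.

Instead of deleting nodes, an attack randomises a fraction of edge
weights, replacing them with fresh Uniform(0, 1) draws.  Random attacks
pick pairs uniformly; targeted attacks restrict to pairs adjacent to hub
nodes — nodes whose mean adjacent weight exceeds the across-node mean by
more than one standard deviation.  Network size is always preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import WeightedNetwork, as_weight_matrix, child_rng, n_pairs

__all__ = [
    "AttackSpec",
    "hub_nodes",
    "random_attack",
    "targeted_attack",
    "RandomAttack",
    "TargetedAttack",
]


@dataclass
class AttackSpec:
    """Attack parameters: kind ('random'|'targeted'), density in [0, 1], seed."""

    kind: str
    density: float
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("random", "targeted"):
            raise ValueError(f"kind must be 'random' or 'targeted', got {self.kind!r}")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError(f"density must lie in [0, 1], got {self.density}")


def hub_nodes(W) -> np.ndarray:
    """Nodes whose mean adjacent weight is > 1 SD above the across-node mean.

    May be empty (e.g. for a uniform-weight complete graph).
    """
    Wm = as_weight_matrix(W)
    n = Wm.shape[0]
    node_strength = Wm.sum(axis=1) / (n - 1)
    threshold = node_strength.mean() + node_strength.std()
    return np.flatnonzero(node_strength > threshold)


def _replace_pairs(Wm: np.ndarray, rows: np.ndarray, cols: np.ndarray, rng) -> np.ndarray:
    out = Wm.copy()
    new = rng.uniform(0.0, 1.0, size=rows.size)
    out[rows, cols] = new
    out[cols, rows] = new
    return out


def random_attack(W, spec: AttackSpec, rng: np.random.Generator | None = None) -> WeightedNetwork:
    """Replace round(density * n(n-1)/2) uniformly chosen pair weights."""
    Wm = as_weight_matrix(W)
    n = Wm.shape[0]
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    P = n_pairs(n)
    k = int(round(spec.density * P))
    if k == 0:
        return WeightedNetwork(Wm.copy())
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.choice(P, size=k, replace=False)
    return WeightedNetwork(_replace_pairs(Wm, iu[pick], ju[pick], rng))


def targeted_attack(
    W,
    spec: AttackSpec,
    rng: np.random.Generator | None = None,
    denominator: str = "hub",
) -> WeightedNetwork:
    """Randomise weights on pairs adjacent to hub nodes.

    The candidate set is every pair with at least one endpoint in
    :func:`hub_nodes`.  With ``denominator="hub"`` (default) the number of
    attacked pairs is round(density * |candidates|), so density 1 means
    "all hub edges randomised"; ``denominator="global"`` reads density as
    a fraction of all pairs, capped at the candidate-set size.  If no
    hubs exist the network is returned unchanged with a warning.
    """
    Wm = as_weight_matrix(W)
    n = Wm.shape[0]
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    hubs = hub_nodes(Wm)
    if hubs.size == 0:
        warnings.warn("no hub nodes found; targeted attack leaves the network unchanged", stacklevel=2)
        return WeightedNetwork(Wm.copy())
    iu, ju = np.triu_indices(n, k=1)
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True
    cand = np.flatnonzero(is_hub[iu] | is_hub[ju])
    if denominator == "hub":
        k = int(round(spec.density * cand.size))
    elif denominator == "global":
        k = min(int(round(spec.density * n_pairs(n))), cand.size)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if k == 0:
        return WeightedNetwork(Wm.copy())
    pick = rng.choice(cand, size=k, replace=False)
    return WeightedNetwork(_replace_pairs(Wm, iu[pick], ju[pick], rng))


class _BaseAttack(BaseEstimator, TransformerMixin):
    """Transformer applying an attack to each matrix in a stack.

    Each input gets its own child generator derived from ``seed``, so a
    stack transform is reproducible and independent of batch order.
    """

    kind = "random"

    def __init__(self, density: float = 0.5, seed: int | None = None):
        self.density = density
        self.seed = seed

    def fit(self, X, y=None):
        AttackSpec(self.kind, self.density, self.seed)  # validate
        return self

    def _attack_one(self, W, rng) -> np.ndarray:
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        if isinstance(X, (WeightedNetwork, np.ndarray)) and getattr(X, "ndim", 2) == 2:
            X = [X]
        elif isinstance(X, np.ndarray) and X.ndim == 3:
            X = list(X)
        out = []
        for i, W in enumerate(X):
            out.append(self._attack_one(W, child_rng(self.seed, i)))
        return np.stack(out)


class RandomAttack(_BaseAttack):
    kind = "random"

    def _attack_one(self, W, rng):
        return random_attack(W, AttackSpec(self.kind, self.density), rng=rng).weights


class TargetedAttack(_BaseAttack):
    kind = "targeted"

    def __init__(self, density: float = 0.5, seed: int | None = None, denominator: str = "hub"):
        super().__init__(density=density, seed=seed)
        self.denominator = denominator

    def _attack_one(self, W, rng):
        return targeted_attack(
            W, AttackSpec(self.kind, self.density), rng=rng, denominator=self.denominator
        ).weights
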