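"""Weighted Complex Hierarchy (WCH) network generator.

The WCH model is a generative weighted network that mimics the hierarchical
hub structure of EEG phase-based functional connectivity.  Every unordered
node pair carries a base weight drawn i.i.d. Uniform(0, 1) (the edge
existence probabilities of an Erdős–Rényi graph read as weights).  Nodes
are assigned to ``h`` hierarchy levels (h drawn uniformly from {2..5} when
unspecified) by independent truncated-geometric draws, and every edge is
topped up by the level contribution of both endpoints::

    w̄_ij = w_ij + (h(i) - 1) s + (h(j) - 1) s

The strength parameter ``s`` tunes how rigid the hierarchy is: s = 0 gives
a uniformly weighted random network, s = 1 a strict class-based topology.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple, Union

import numpy as np

from .core import WeightedNetwork, child_rng

__all__ = [
    "WchSpec",
    "HierarchyAssignment",
    "assign_levels",
    "generate_wch",
    "build_bank",
    "weight_ceiling",
]

_H_CHOICES = (2, 3, 4, 5)


def weight_ceiling(s: float, h_max: int = _H_CHOICES[-1]) -> float:
    """Largest weight attainable in the model family: 1 + 2(h_max - 1)s.

    Dividing a WCH matrix by this constant maps it into [0, 1] — the
    scale on which weighted analyses and the shortest-path log transform
    operate — without touching edge ranks, so rank-based binarisations
    are unaffected.
    """
    return 1.0 + 2.0 * (h_max - 1) * s


@dataclass
class WchSpec:
    """Parameters of one WCH realisation.

    Parameters
    ----------
    n
        Node count (>= 2).
    s
        Hierarchy strength (>= 0); each edge gains (h(i)-1)s + (h(j)-1)s.
    h
        Number of hierarchy levels: an integer in [2, 5], or ``"random"``
        to draw uniformly from {2, 3, 4, 5} per realisation.
    level_param
        Success probability of the geometric level assignment, in (0, 1).
        The fraction of nodes at level 1 is level_param in expectation.
    seed
        RNG seed; fixing it makes the realisation reproducible.
    """

    n: int
    s: float
    h: Union[int, str] = "random"
    level_param: float = 0.6
    seed: int | None = None

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"n must be an integer >= 2, got {self.n}")
        self.n = int(self.n)
        if self.s < 0:
            raise ValueError(f"s must be >= 0, got {self.s}")
        if self.h != "random":
            if int(self.h) != self.h or not (2 <= int(self.h) <= 5):
                raise ValueError(f"h must be 'random' or an integer in [2, 5], got {self.h}")
            self.h = int(self.h)
        if not (0.0 < self.level_param < 1.0):
            raise ValueError(f"level_param must lie in (0, 1), got {self.level_param}")


@dataclass
class HierarchyAssignment:
    """Node-to-level map: ``levels[i]`` is h(i), an integer in [1, h]."""

    levels: np.ndarray
    h: int

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.ndim != 1:
            raise ValueError("levels must be a vector")
        if self.levels.size and (self.levels.min() < 1 or self.levels.max() > self.h):
            raise ValueError("every level must lie in [1, h]")


def assign_levels(
    n: int, h: int, level_param: float = 0.6, rng: np.random.Generator | None = None
) -> HierarchyAssignment:
    """Assign each of ``n`` nodes a hierarchy level in [1, h].

    Each node independently receives min(G, h), where G is geometric on
    {1, 2, ...} with success probability ``level_param``: excess geometric
    mass is lumped into the deepest level rather than renormalised, so the
    level-1 occupancy probability stays exactly ``level_param``.  Empty
    levels are permitted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (2 <= h <= 5):
        raise ValueError(f"h must lie in [2, 5], got {h}")
    if not (0.0 < level_param < 1.0):
        raise ValueError(f"level_param must lie in (0, 1), got {level_param}")
    rng = np.random.default_rng() if rng is None else rng
    g = rng.geometric(level_param, size=n)
    return HierarchyAssignment(levels=np.minimum(g, h), h=h)


def generate_wch(
    spec: WchSpec, rng: np.random.Generator | None = None
) -> Tuple[WeightedNetwork, HierarchyAssignment]:
    """Draw one WCH realisation.

    Returns the weighted network and the realised hierarchy assignment.
    Reproducible under a fixed ``spec.seed`` (ignored if ``rng`` is given).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h = int(rng.integers(_H_CHOICES[0], _H_CHOICES[-1] + 1)) if spec.h == "random" else spec.h
    assignment = assign_levels(spec.n, h, spec.level_param, rng)

    n = spec.n
    base = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    base[iu] = rng.uniform(0.0, 1.0, size=iu[0].size)
    base += base.T

    add = (assignment.levels - 1) * spec.s
    # sum the two level contributions first so W is exactly symmetric
    W = base + (add[:, None] + add[None, :])
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork(W), assignment


def build_bank(
    spec: WchSpec, bank_size: int, return_assignments: bool = False
) -> Union[List[WeightedNetwork], Tuple[List[WeightedNetwork], List[HierarchyAssignment]]]:
    """Generate ``bank_size`` independent WCH realisations.

    Per-network seeds are derived from ``spec.seed`` by a counter-based
    spawn scheme, so the k-th member of a bank is identical no matter the
    bank size, and two banks built from the same spec are bit-identical.
    """
    if bank_size < 1:
        raise ValueError("bank_size must be >= 1")
    nets, assignments = [], []
    for k in range(bank_size):
        net, asg = generate_wch(spec, rng=child_rng(spec.seed, k))
        nets.append(net)
        assignments.append(asg)
    if return_assignments:
        return nets, assignments
    return nets
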