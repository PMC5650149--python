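"""Readers, writers and the deterministic fixture generator.

Weight matrices travel as header-less delimited text (comma, tab or
whitespace sniffed on read; comma on write) or GraphML with a ``weight``
edge attribute.  Hierarchy assignments are two-column CSV (node, level).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import WeightedNetwork
from .wch import WchSpec, build_bank

__all__ = [
    "read_weighted",
    "write_weighted",
    "write_levels",
    "read_signals",
    "make_fixtures",
    "TOY_WEIGHTS_4",
]

# 4-node toy matrix used throughout the docs and tests
# (edges ab:0.9 ac:0.8 ad:0.1 bc:0.2 bd:0.3 cd:0.4)
TOY_WEIGHTS_4 = np.array(
    [
        [0.0, 0.9, 0.8, 0.1],
        [0.9, 0.0, 0.2, 0.3],
        [0.8, 0.2, 0.0, 0.4],
        [0.1, 0.3, 0.4, 0.0],
    ]
)


def _sniff_delimiter(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if "," in line:
                    return ","
                if "\t" in line:
                    return "\t"
                return None  # whitespace
    raise ValueError(f"{path}: file is empty")


def read_weighted(path) -> WeightedNetwork:
    """Read a weight matrix from delimited text or GraphML.

    Asymmetries above 1e-8 and nonzero diagonals are repaired with a
    warning (symmetrised as (W + W.T)/2, diagonal zeroed).
    """
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        G = nx.read_graphml(path)
        nodes = list(G.nodes())
        W = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
        labels = nodes
    else:
        delim = _sniff_delimiter(path)
        try:
            W = np.loadtxt(path, delimiter=delim, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric entry in matrix file ({exc})") from exc
        labels = None
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{path}: matrix must be square, got {W.shape[0]} rows x {W.shape[1]} columns")
    if np.any(~np.isfinite(W)):
        rows, cols = np.nonzero(~np.isfinite(W))
        raise ValueError(f"{path}: non-finite entry at row {rows[0]}, column {cols[0]}")
    asym = np.abs(W - W.T).max()
    if asym > 1e-8:
        warnings.warn(f"{path}: matrix asymmetric (max deviation {asym:.3g}); symmetrising", stacklevel=2)
    W = (W + W.T) / 2.0
    if np.any(np.diag(W) != 0):
        warnings.warn(f"{path}: nonzero diagonal zeroed", stacklevel=2)
        np.fill_diagonal(W, 0.0)
    return WeightedNetwork(W, node_labels=labels)


def write_weighted(W: WeightedNetwork | np.ndarray, path, fmt: str = "csv") -> None:
    """Write a weight matrix as comma-delimited text or GraphML."""
    path = Path(path)
    net = W if isinstance(W, WeightedNetwork) else WeightedNetwork(np.asarray(W, float))
    if fmt == "graphml" or path.suffix.lower() == ".graphml":
        G = nx.from_numpy_array(net.weights)
        if net.node_labels is not None:
            G = nx.relabel_nodes(G, dict(enumerate(net.node_labels)))
        nx.write_graphml(G, path)
    else:
        np.savetxt(path, net.weights, delimiter=",", fmt="%.17g")


def write_levels(levels: np.ndarray, path) -> None:
    pd.DataFrame({"node": np.arange(len(levels)), "level": np.asarray(levels, int)}).to_csv(
        path, index=False
    )


def read_signals(path, fs: float | None = None):
    """Read a channels x samples delimited-text matrix, with optional YAML sidecar.

    A sidecar ``<name>.yaml`` next to the file may carry ``fs`` and
    ``labels``; an explicit ``fs`` argument wins.
    """
    import yaml

    from .connectivity import SignalSet

    path = Path(path)
    delim = _sniff_delimiter(path)
    data = np.loadtxt(path, delimiter=delim, ndmin=2)
    labels = None
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        fs = fs if fs is not None else meta.get("fs")
        labels = meta.get("labels")
    if fs is None:
        raise ValueError(f"{path}: sampling rate not given and no YAML sidecar found")
    return SignalSet(data, fs=float(fs), channel_labels=labels)


def write_provenance(path, **record) -> None:
    """Dump a JSON provenance record (config snapshot, seed, version)."""
    from . import __version__

    record.setdefault("netbin_version", __version__)
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")


def make_fixtures(kind: str, seed: int, outdir) -> list:
    """Write small deterministic fixtures for tests and examples.

    Kinds: ``wch-banks`` (a 16-node mini-bank), ``toy-weights`` (the
    4-node matrix above), ``oscillator-signals`` (4 coupled channels with
    planted lags plus 2 noise channels, 250 Hz).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if kind == "wch-banks":
        bank, assignments = build_bank(
            WchSpec(n=16, s=0.1, seed=seed), bank_size=5, return_assignments=True
        )
        for k, (net, asg) in enumerate(zip(bank, assignments)):
            p = outdir / f"wch16_s0.1_{k}.csv"
            write_weighted(net, p)
            write_levels(asg.levels, outdir / f"wch16_s0.1_{k}_levels.csv")
            written.extend([p, outdir / f"wch16_s0.1_{k}_levels.csv"])
    elif kind == "toy-weights":
        p = outdir / "toy4.csv"
        write_weighted(TOY_WEIGHTS_4, p)
        written.append(p)
    elif kind == "oscillator-signals":
        rng = np.random.default_rng(seed)
        fs, T, f0 = 250.0, 2000, 10.0
        t = np.arange(T) / fs
        base = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        lagged = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi) + np.pi / 4)
        sigs = np.vstack(
            [
                base + 0.1 * rng.standard_normal(T),
                np.roll(base, 5) + 0.1 * rng.standard_normal(T),
                lagged + 0.1 * rng.standard_normal(T),
                np.roll(lagged, 5) + 0.1 * rng.standard_normal(T),
                rng.standard_normal(T),
                rng.standard_normal(T),
            ]
        )
        p = outdir / "oscillators.csv"
        np.savetxt(p, sigs, delimiter=",", fmt="%.8g")
        (outdir / "oscillators.yaml").write_text(
            "fs: 250\nlabels: [osc1a, osc1b, osc2a, osc2b, noise1, noise2]\n"
        )
        written.extend([p, outdir / "oscillators.yaml"])
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
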