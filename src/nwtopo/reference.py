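"""Reference graphs: Watts–Strogatz sweep, layered ANN, connectome loading.

These are the comparison families the nanowire networks are measured
against: ring lattices rewired toward randomness (grid-like at beta=0,
random at beta=1), an untrained fully-connected feed-forward network
treated purely as a topology, and the *C. elegans* structural connectome
(or a synthetic stand-in with similar gross statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError


@dataclass(frozen=True)
class WSParams:
    """Watts–Strogatz parameters: N nodes, k neighbours per side (mean
    degree 2k), rewiring probability beta."""

    n_nodes: int
    k: int
    beta: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if 2 * self.k >= self.n_nodes:
            raise ParameterError(
                f"need 2k < N, got k={self.k}, N={self.n_nodes}"
            )
        if not 0.0 <= self.beta <= 1.0:
            raise ParameterError("beta must lie in [0, 1]")


@dataclass(frozen=True)
class LayeredAnnSpec:
    layer_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ParameterError("need at least 2 layers")
        if any(s < 1 for s in self.layer_sizes):
            raise ParameterError("layer sizes must be positive")


@dataclass
class Connectome:
    node_labels: list[str]
    graph: nx.Graph


def watts_strogatz(params: WSParams) -> nx.Graph:
    """Ring lattice of mean degree 2k with each edge rewired w.p. beta.

    Rewiring replaces the far endpoint of a lattice edge with a uniformly
    chosen node, rejecting self-loops and duplicates, so the edge count is
    exactly N*k at every beta.  beta=0 is the deterministic ring lattice.
    """
    return nx.watts_strogatz_graph(
        params.n_nodes, 2 * params.k, params.beta, seed=params.seed
    )


def k_from_mean_degree(mean_degree: float) -> int:
    """Half the mean degree, rounded to the nearest integer (ties to
    even), floored at 1."""
    return max(1, round(mean_degree / 2.0))


def matched_ws(target_graph: nx.Graph, beta: float, seed: int = 0) -> nx.Graph:
    """A WS graph with N and mean degree matched to ``target_graph``."""
    n = target_graph.number_of_nodes()
    if n < 3:
        raise ParameterError("target graph must have >= 3 nodes")
    md = 2.0 * target_graph.number_of_edges() / n
    k = k_from_mean_degree(md)
    return watts_strogatz(WSParams(n_nodes=n, k=k, beta=beta, seed=seed))


def beta_sweep(step: float = 0.05) -> list[float]:
    """Rewiring probabilities 0, step, ..., 1 (21 values at the default)."""
    n_steps = int(round(1.0 / step))
    return [round(i * step, 10) for i in range(n_steps + 1)]


def layered_ann(spec: LayeredAnnSpec) -> nx.Graph:
    """Fully-connected layered feed-forward topology.

    Consecutive layers are joined completely bipartitely; there are no
    within-layer edges, so the graph is triangle-free and every node has
    clustering coefficient 0.
    """
    g = nx.Graph()
    offsets = np.concatenate([[0], np.cumsum(spec.layer_sizes)])
    g.add_nodes_from(range(int(offsets[-1])))
    for li in range(len(spec.layer_sizes) - 1):
        a = range(int(offsets[li]), int(offsets[li + 1]))
        b = range(int(offsets[li + 1]), int(offsets[li + 2]))
        g.add_edges_from((u, v) for u in a for v in b)
    return g


def _clean(graph: nx.Graph) -> nx.Graph:
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def load_connectome(path: str | Path, format: str | None = None) -> Connectome:
    """Load an external connectome file as an undirected simple graph.

    Accepted formats: two-column edge list (``edgelist``; tab, comma or
    whitespace separated, optional third weight column) and square
    adjacency matrix CSV with labels in the first row and column
    (``matrix``).  Directed or weighted input is symmetrized and
    binarized; self-loops are dropped and parallel entries merged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "matrix" if path.suffix.lower() in {".csv", ".mat"} else "edgelist"
    if format == "edgelist":
        try:
            df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
        except Exception as exc:  # noqa: BLE001 - report as a format problem
            raise FormatError(f"could not parse edge list {path}: {exc}") from exc
        if df.shape[1] < 2:
            raise FormatError("edge list needs at least two columns")
        g = nx.Graph()
        g.add_edges_from(
            (str(u), str(v)) for u, v in zip(df.iloc[:, 0], df.iloc[:, 1])
        )
        g = _clean(g)
    elif format == "matrix":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not parse adjacency matrix {path}: {exc}") from exc
        if df.shape[0] != df.shape[1]:
            raise FormatError(
                f"adjacency matrix must be square, got {df.shape[0]}x{df.shape[1]}"
            )
        labels = [str(x) for x in df.index]
        a = df.to_numpy(dtype=float)
        a = (a != 0) | (a.T != 0)  # symmetrize + binarize
        np.fill_diagonal(a, False)
        g = nx.Graph()
        g.add_nodes_from(labels)
        iu, ju = np.nonzero(np.triu(a, 1))
        g.add_edges_from((labels[i], labels[j]) for i, j in zip(iu, ju))
    else:
        raise FormatError(f"unknown connectome format: {format!r}")
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise FormatError(f"{path} yielded an empty graph")
    return Connectome(node_labels=sorted(g.nodes), graph=g)


def synthetic_connectome(
    n_nodes: int = 277,
    n_edges: int = 2105,
    hub_fraction: float = 0.1,
    seed: int = 0,
) -> Connectome:
    """Synthetic connectome-like fixture: connected, modular, with hubs.

    This is a constructed stand-in with the gross statistics of a small
    nervous system (node/edge count, community structure, a minority of
    high-degree hub neurons), not real anatomical data.  Nodes are split
    into modules, each module wired as a random path (guaranteeing
    connectivity) and the modules chained; remaining edges are sampled
    mostly within modules, with endpoint probabilities biased toward the
    designated hub nodes.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (n_nodes - 1 <= n_edges <= max_edges):
        raise ParameterError(
            f"n_edges={n_edges} infeasible for a connected simple graph on "
            f"{n_nodes} nodes"
        )
    if not 0.0 <= hub_fraction <= 1.0:
        raise ParameterError("hub_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_modules = max(2, round(n_nodes / 25))
    order = rng.permutation(n_nodes)
    modules = [list(map(int, order[m::n_modules])) for m in range(n_modules)]

    edges: set[tuple[int, int]] = set()

    def add(u: int, v: int) -> None:
        if u != v:
            edges.add((min(u, v), max(u, v)))

    for members in modules:
        chain = rng.permutation(members)
        for u, v in zip(chain[:-1], chain[1:]):
            add(int(u), int(v))
    for ma, mb in zip(modules[:-1], modules[1:]):
        add(int(rng.choice(ma)), int(rng.choice(mb)))

    n_hubs = int(round(hub_fraction * n_nodes))
    weight = np.ones(n_nodes)
    if n_hubs:
        weight[rng.choice(n_nodes, size=n_hubs, replace=False)] = 8.0
    weight /= weight.sum()
    module_of = np.empty(n_nodes, dtype=int)
    for m, members in enumerate(modules):
        module_of[members] = m

    while len(edges) < n_edges:
        u = int(rng.choice(n_nodes, p=weight))
        if rng.random() < 0.75:
            v = int(rng.choice(modules[module_of[u]]))
        else:
            v = int(rng.choice(n_nodes, p=weight))
        add(u, v)

    labels = [f"n{i:03d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from((labels[u], labels[v]) for u, v in edges)
    return Connectome(node_labels=labels, graph=g)
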