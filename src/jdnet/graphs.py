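"""Fixed-density binary networks and small-world metrics.

A weighted coupling matrix is binarized by keeping a fixed proportion of the
strongest node pairs, so every subject's graph has exactly the same edge
count and metrics are comparable across subjects. Clustering, characteristic
path length and eccentricity are computed on the binary graph; the
small-world quotient normalizes clustering and path length by their means
over ten Erdos-Renyi style reference graphs of identical size:

    Q = (C_actual / C_random) / (L_actual / L_random).

Disconnected graphs can occur at sparse densities; shortest-path metrics are
then taken on the largest connected component (a documented convention; the
component size is reported alongside the metrics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import UndefinedMetricError

__all__ = [
    "BinaryNetwork",
    "RandomReference",
    "NetworkMetrics",
    "edge_count_for_density",
    "binarize_fixed_density",
    "largest_component",
    "clustering_coefficient",
    "characteristic_path_length",
    "eccentricity",
    "random_reference",
    "small_world_q",
    "network_metrics",
]


@dataclass
class BinaryNetwork:
    """Undirected unweighted graph at a fixed edge density."""

    graph: nx.Graph
    density: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class RandomReference:
    """Mean clustering / path length over uniform-random reference graphs."""

    n_graphs: int
    c_random: float
    l_random: float
    seed: int | None = None
    c_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    l_values: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class NetworkMetrics:
    """Per-subject graph metrics plus the normalized small-world quotient."""

    c_actual: float
    l_actual: float
    eccentricity: float
    q: float
    c_random: float
    l_random: float
    n_nodes: int
    n_edges: int
    component_size: int
    eccentricity_by_node: dict = field(default_factory=dict)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def edge_count_for_density(n_nodes: int, density: float) -> int:
    """Edges kept at a given density over node pairs (round half away)."""
    return _round_half_away(density * n_nodes * (n_nodes - 1) / 2.0)


def _top_pairs(w: np.ndarray, n_edges: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the strongest off-diagonal pairs; ties broken by (row, col)."""
    rows, cols = np.triu_indices(w.shape[0], k=1)
    weights = w[rows, cols]
    order = np.lexsort((cols, rows, -weights))[:n_edges]
    return rows[order], cols[order]


def binarize_fixed_density(w: np.ndarray, density: float = 0.10) -> BinaryNetwork:
    """Keep the strongest ``round(density * V(V-1)/2)`` pairs as edges.

    The weight matrix must be symmetric with a zero (ignored) diagonal.
    Threshold ties are broken deterministically by lexicographic
    (row, column) order so quantized weights reproduce exactly.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = w.shape[0]
    n_edges = edge_count_for_density(n, density)
    g = nx.empty_graph(n)
    rows, cols = _top_pairs(w, n_edges)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return BinaryNetwork(graph=g, density=density)


def _as_graph(g: BinaryNetwork | nx.Graph) -> nx.Graph:
    return g.graph if isinstance(g, BinaryNetwork) else g


def largest_component(g: BinaryNetwork | nx.Graph) -> nx.Graph:
    """Subgraph on the largest connected component (ties: smallest label)."""
    graph = _as_graph(g)
    if graph.number_of_nodes() == 0:
        raise UndefinedMetricError("empty graph")
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    return graph.subgraph(comps[0])


def clustering_coefficient(g: BinaryNetwork | nx.Graph) -> tuple[dict, float]:
    """Per-node clustering (degree < 2 gives 0) and its mean over all nodes."""
    graph = _as_graph(g)
    per_node = nx.clustering(graph)
    mean = float(np.mean(list(per_node.values()))) if per_node else 0.0
    return per_node, mean


def characteristic_path_length(g: BinaryNetwork | nx.Graph) -> float:
    """Mean shortest-path length over reachable pairs (largest component)."""
    comp = largest_component(g)
    if comp.number_of_nodes() < 2:
        raise UndefinedMetricError(
            "largest component has < 2 nodes; path length undefined"
        )
    return float(nx.average_shortest_path_length(comp))


def eccentricity(
    g: BinaryNetwork | nx.Graph, summary: str = "mean"
) -> tuple[dict, float]:
    """Per-node eccentricity (within each node's own component) and a summary.

    Isolated nodes get eccentricity 0. The subject-level summary is taken
    over the largest connected component: ``"mean"`` (default) or ``"max"``
    (the component diameter), matching the component convention used for
    path length.
    """
    graph = _as_graph(g)
    per_node: dict = {}
    for comp_nodes in nx.connected_components(graph):
        sub = graph.subgraph(comp_nodes)
        if sub.number_of_nodes() == 1:
            per_node[next(iter(comp_nodes))] = 0
        else:
            per_node.update(nx.eccentricity(sub))
    lcc = largest_component(graph)
    vals = [per_node[v] for v in lcc.nodes]
    if summary == "mean":
        stat = float(np.mean(vals))
    elif summary == "max":
        stat = float(np.max(vals))
    else:
        raise ValueError("summary must be 'mean' or 'max'")
    return per_node, stat


def random_reference(
    n_nodes: int,
    n_edges: int,
    n_rand: int = 10,
    seed: int | None = None,
) -> RandomReference:
    """Reference clustering / path length from uniform-random graphs.

    Each reference is a symmetric matrix of independent uniform weights
    binarized at the same edge count — equivalently a uniform-random
    ``n_edges``-edge graph. Metrics are averaged over ``n_rand`` graphs
    (10 by default) and are fully reproducible from ``seed``.
    """
    if n_rand < 1:
        raise ValueError("need at least one reference graph")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"edge count {n_edges} outside [0, {max_edges}]")
    rng = np.random.default_rng(seed)
    c_vals = np.empty(n_rand)
    l_vals = np.empty(n_rand)
    for k in range(n_rand):
        w = rng.uniform(size=(n_nodes, n_nodes))
        w = np.triu(w, 1)
        w = w + w.T
        rows, cols = _top_pairs(w, n_edges)
        g = nx.empty_graph(n_nodes)
        g.add_edges_from(zip(rows.tolist(), cols.tolist()))
        _, c_vals[k] = clustering_coefficient(g)
        l_vals[k] = characteristic_path_length(g)
    return RandomReference(
        n_graphs=n_rand,
        c_random=float(c_vals.mean()),
        l_random=float(l_vals.mean()),
        seed=seed,
        c_values=c_vals,
        l_values=l_vals,
    )


def small_world_q(c_a: float, c_r: float, l_a: float, l_r: float) -> float:
    """Small-world quotient ``(C_a / C_r) / (L_a / L_r)``."""
    if c_r <= 0 or l_r <= 0 or l_a <= 0:
        raise UndefinedMetricError("small-world quotient needs positive inputs")
    return (c_a / c_r) / (l_a / l_r)


def network_metrics(
    w: np.ndarray,
    density: float = 0.10,
    n_rand: int = 10,
    seed: int | None = None,
    ecc_summary: str = "mean",
) -> NetworkMetrics:
    """Binarize a coupling matrix and compute the full metric set."""
    net = binarize_fixed_density(w, density)
    _, c_actual = clustering_coefficient(net)
    l_actual = characteristic_path_length(net)
    ecc_by_node, ecc = eccentricity(net, summary=ecc_summary)
    ref = random_reference(net.n_nodes, net.n_edges, n_rand=n_rand, seed=seed)
    q = small_world_q(c_actual, ref.c_random, l_actual, ref.l_random)
    return NetworkMetrics(
        c_actual=c_actual,
        l_actual=l_actual,
        eccentricity=ecc,
        q=q,
        c_random=ref.c_random,
        l_random=ref.l_random,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        component_size=largest_component(net).number_of_nodes(),
        eccentricity_by_node=ecc_by_node,
    )
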