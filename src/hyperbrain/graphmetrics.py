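"""Topology metrics of the binary hyperbrain graph.

Metrics (computed with networkx on the full node set, isolated nodes
included, since one combined network is built per dyad):

* edge number EN — count of undirected edges (each unordered connected
  pair once);
* global efficiency GE — mean over ordered node pairs of the inverse
  shortest-path hop count, with 1/inf = 0 for unreachable pairs;
* local efficiency LE — mean over nodes of the global efficiency of the
  subgraph induced by each node's neighbors (degree < 2 contributes 0);
* modularity Q — Newman's Q for the FIXED two-module partition given by
  participant membership (no community detection): high Q means the two
  brains are nearly disconnected, low Q a dense inter-brain coupling;
* characteristic path length — mean shortest path over reachable ordered
  pairs (the unreachable fraction is reported alongside);
* clustering coefficient — mean over nodes of the triangle density among
  neighbors (degree < 2 contributes 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .surrogate import HyperbrainGraph


class UndefinedMetricError(ValueError):
    pass


@dataclass
class GraphMetricsResult:
    """All topology metrics of one hyperbrain graph."""

    edge_number: int
    global_efficiency: float
    local_efficiency: float
    modularity: float
    char_path_length: float
    clustering_coefficient: float
    s: int
    degrees: np.ndarray
    fraction_unreachable: float


def _as_nx(g: HyperbrainGraph) -> nx.Graph:
    graph = nx.from_numpy_array(np.asarray(g.adjacency))
    graph.add_nodes_from(range(g.n_nodes))
    return graph


def edge_number(g: HyperbrainGraph) -> int:
    """Number of undirected edges (each connected unordered pair once)."""
    return int(np.triu(g.adjacency, k=1).sum())


def shortest_paths(g: HyperbrainGraph) -> np.ndarray:
    """Pairwise hop-count matrix; unreachable pairs are ``inf``, diagonal 0."""
    graph = _as_nx(g)
    n = g.n_nodes
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        for dst, d in lengths.items():
            dist[src, dst] = d
    return dist


def global_efficiency(g: HyperbrainGraph) -> float:
    if g.n_nodes < 2:
        raise UndefinedMetricError("global efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(_as_nx(g)))


def local_efficiency(g: HyperbrainGraph) -> float:
    return float(nx.local_efficiency(_as_nx(g)))


def modularity(g: HyperbrainGraph, module_of: np.ndarray | None = None) -> float:
    """Newman's Q against the fixed participant partition."""
    if edge_number(g) == 0:
        raise UndefinedMetricError("modularity undefined for an empty graph")
    modules = g.module_of if module_of is None else np.asarray(module_of)
    graph = _as_nx(g)
    communities = [
        {i for i in range(g.n_nodes) if modules[i] == label}
        for label in np.unique(modules)
    ]
    return float(nx.community.modularity(graph, communities))


def char_path_length(g: HyperbrainGraph) -> tuple[float, float]:
    """Mean shortest path over reachable ordered pairs, plus the unreachable fraction."""
    dist = shortest_paths(g)
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_off = off.sum()
    if not finite.any():
        raise UndefinedMetricError("no reachable node pair; path length undefined")
    return float(dist[finite].mean()), float(1.0 - finite.sum() / n_off)


def clustering_coefficient(g: HyperbrainGraph) -> float:
    """Mean local clustering; nodes of degree < 2 contribute 0."""
    return float(nx.average_clustering(_as_nx(g)))


def compute_graph_metrics(g: HyperbrainGraph) -> GraphMetricsResult:
    """All metrics of one graph in a single result row."""
    en = edge_number(g)
    degrees = np.asarray(g.adjacency).sum(axis=0)
    try:
        pl, frac_unreach = char_path_length(g)
    except UndefinedMetricError:
        pl, frac_unreach = math.inf, 1.0
    try:
        q = modularity(g)
    except UndefinedMetricError:
        q = math.nan
    return GraphMetricsResult(
        edge_number=en,
        global_efficiency=global_efficiency(g),
        local_efficiency=local_efficiency(g),
        modularity=q,
        char_path_length=pl,
        clustering_coefficient=clustering_coefficient(g),
        s=g.n_nodes,
        degrees=degrees,
        fraction_unreachable=frac_unreach,
    )
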