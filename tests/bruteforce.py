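"""Independent brute-force graph-metric implementations used as test oracles.

These deliberately avoid networkx: shortest paths via Floyd-Warshall on the
adjacency matrix, efficiencies and modularity via direct summation of their
defining formulas. They are O(n^3)-ish and only meant for small graphs.
"""

from __future__ import annotations

import numpy as np


def fw_shortest_paths(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall hop counts; inf for unreachable, 0 diagonal."""
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    return dist


def ge_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = fw_shortest_paths(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def le_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        d_i = nbrs.size
        if d_i < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        dist = fw_shortest_paths(sub)
        acc = 0.0
        for a in range(d_i):
            for b in range(d_i):
                if a != b and np.isfinite(dist[a, b]):
                    acc += 1.0 / dist[a, b]
        total += acc / (d_i * (d_i - 1))
    return total / n


def q_oracle(adj: np.ndarray, modules: np.ndarray) -> float:
    deg = adj.sum(axis=0)
    two_m = adj.sum()
    n = adj.shape[0]
    q = 0.0
    for i in range(n):
        for k in range(n):
            if modules[i] == modules[k]:
                q += adj[i, k] - deg[i] * deg[k] / two_m
    return q / two_m


def cpl_oracle(adj: np.ndarray) -> float:
    dist = fw_shortest_paths(adj)
    n = adj.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(dist[i, j])]
    return float(np.mean(vals))


def cc_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        d_i = nbrs.size
        if d_i < 2:
            continue
        links = adj[np.ix_(nbrs, nbrs)].sum() / 2.0
        total += 2.0 * links / (d_i * (d_i - 1))
    return total / n
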