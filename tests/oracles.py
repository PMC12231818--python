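"""Independent brute-force oracles used across the test suite.

These deliberately share no code with the package: BFS over explicit queues,
triangle counting by neighbor enumeration, and a literal step-up
implementation of Benjamini-Hochberg.
"""

from collections import deque

import numpy as np


def bfs_distances(adj, source):
    n = adj.shape[0]
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u, v] and v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_force_nodal_metrics(adj):
    """degree, clustering, path_length, efficiency by direct enumeration."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    degree = np.zeros(n, dtype=int)
    clustering = np.zeros(n)
    path_length = np.full(n, np.nan)
    efficiency = np.zeros(n)
    for u in range(n):
        neighbors = [v for v in range(n) if adj[u, v]]
        k = len(neighbors)
        degree[u] = k
        if k >= 2:
            links = sum(
                1
                for i in range(k)
                for j in range(i + 1, k)
                if adj[neighbors[i], neighbors[j]]
            )
            clustering[u] = 2.0 * links / (k * (k - 1))
        dist = bfs_distances(adj, u)
        others = [d for v, d in dist.items() if v != u]
        if others:
            path_length[u] = float(np.mean(others))
        efficiency[u] = sum(1.0 / d for d in others) / (n - 1)
    return degree, clustering, path_length, efficiency


def brute_force_char_path_length(adj):
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    dists = []
    for u in range(n):
        dist = bfs_distances(adj, u)
        dists.extend(d for v, d in dist.items() if v != u)
    return float(np.mean(dists))


def bh_adjust_brute(p_values):
    """Literal BH step-up: q_(i) = min_{j >= i} min(1, m * p_(j) / j)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, min(1.0, m * p[idx] / rank))
        adjusted_sorted[rank - 1] = running
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def random_graph_adj(rng, n, p):
    """Random symmetric adjacency without self-loops."""
    upper = np.triu(rng.random((n, n)) < p, 1)
    return upper | upper.T
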