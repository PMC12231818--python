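"""Numba kernels for the numerically hot paths.

Everything here is an implementation detail behind :mod:`iscn.network` and
:mod:`iscn.graphs`; the public API never exposes these functions.  Each kernel
is deliberately simple (no object mode, no parallelism) so results are
bit-reproducible on a single CPU given the integer seed passed in.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@njit(cache=True, fastmath=True)
def kde_gauss_eval(samples, points, bandwidth):
    """Gaussian-kernel density estimate evaluated at ``points``.

    density(x) = (1 / (n h)) * sum_i phi((x - s_i) / h)
    """
    n = samples.shape[0]
    m = points.shape[0]
    out = np.zeros(m)
    inv_h = 1.0 / bandwidth
    for i in range(n):
        s = samples[i]
        for j in range(m):
            z = (points[j] - s) * inv_h
            out[j] += np.exp(-0.5 * z * z)
    norm = 1.0 / (n * bandwidth * _SQRT_2PI)
    for j in range(m):
        out[j] *= norm
    return out


@njit(cache=True)
def double_edge_swap(adj, edges, n_swaps, seed):
    """Maslov–Sneppen degree-preserving rewiring, in place.

    ``n_swaps`` counts *attempted* swaps; proposals creating self-loops or
    multi-edges are rejected (and still count).  Returns the number of
    successful swaps.  ``adj`` is a boolean adjacency matrix and ``edges`` an
    (E, 2) int64 array; both are mutated consistently.
    """
    np.random.seed(seed)
    n_edges = edges.shape[0]
    successes = 0
    for _ in range(n_swaps):
        i = np.random.randint(n_edges)
        j = np.random.randint(n_edges)
        if i == j:
            continue
        a, b = edges[i, 0], edges[i, 1]
        c, d = edges[j, 0], edges[j, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[i, 0] = a
        edges[i, 1] = d
        edges[j, 0] = c
        edges[j, 1] = b
        successes += 1
    return successes


@njit(cache=True)
def _csr_from_edges(n_nodes, edges):
    """Adjacency list (CSR indptr/indices) from an undirected edge array."""
    deg = np.zeros(n_nodes, np.int64)
    for e in range(edges.shape[0]):
        deg[edges[e, 0]] += 1
        deg[edges[e, 1]] += 1
    indptr = np.zeros(n_nodes + 1, np.int64)
    for v in range(n_nodes):
        indptr[v + 1] = indptr[v] + deg[v]
    fill = indptr[:-1].copy()
    indices = np.empty(indptr[n_nodes], np.int64)
    for e in range(edges.shape[0]):
        a, b = edges[e, 0], edges[e, 1]
        indices[fill[a]] = b
        fill[a] += 1
        indices[fill[b]] = a
        fill[b] += 1
    return indptr, indices


@njit(cache=True)
def bfs_mean_path_length(n_nodes, indptr, indices):
    """Mean shortest-path distance over ordered reachable pairs.

    Returns (mean, n_unreachable_ordered_pairs); mean is NaN when no pair is
    reachable.
    """
    total = 0.0
    reachable = 0
    dist = np.empty(n_nodes, np.int64)
    queue = np.empty(n_nodes, np.int64)
    for s in range(n_nodes):
        dist[:] = -1
        dist[s] = 0
        queue[0] = s
        head = 0
        tail = 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for k in range(indptr[u], indptr[u + 1]):
                v = indices[k]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for v in range(n_nodes):
            if v != s and dist[v] > 0:
                total += dist[v]
                reachable += 1
    n_pairs = n_nodes * (n_nodes - 1)
    if reachable == 0:
        return np.nan, n_pairs
    return total / reachable, n_pairs - reachable


@njit(cache=True)
def mean_clustering(adj, indptr, indices):
    """Mean nodal clustering coefficient (0 for degree < 2) over all nodes."""
    n_nodes = adj.shape[0]
    total = 0.0
    for u in range(n_nodes):
        k = indptr[u + 1] - indptr[u]
        if k < 2:
            continue
        links = 0
        for a in range(indptr[u], indptr[u + 1]):
            va = indices[a]
            for b in range(a + 1, indptr[u + 1]):
                if adj[va, indices[b]]:
                    links += 1
        total += 2.0 * links / (k * (k - 1.0))
    return total / n_nodes


@njit(cache=True)
def null_ensemble_stats(adj, edges, n_random, n_swaps, seed):
    """Cp and Lp of ``n_random`` degree-preserving rewired copies of a graph.

    Each replicate starts from the input graph, applies ``n_swaps`` attempted
    double-edge swaps with its own derived seed, and records the mean
    clustering coefficient and the characteristic path length.  Returns
    (cp[n_random], lp[n_random]).
    """
    n_nodes = adj.shape[0]
    cp = np.empty(n_random)
    lp = np.empty(n_random)
    for r in range(n_random):
        a = adj.copy()
        e = edges.copy()
        double_edge_swap(a, e, n_swaps, (seed + 9973 * r) % 2147483647)
        indptr, indices = _csr_from_edges(n_nodes, e)
        cp[r] = mean_clustering(a, indptr, indices)
        lp[r], _ = bfs_mean_path_length(n_nodes, indptr, indices)
    return cp, lp
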