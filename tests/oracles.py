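"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (Floyd-Warshall
distances, Brandes betweenness with explicit predecessor lists, exhaustive
threshold scans) so they share no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np

EDGE_LENGTH_EPS = 1e-6


def length_matrix(weights: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Edge lengths 1/(w+eps) for retained edges, inf elsewhere."""
    V = weights.shape[0]
    L = np.full((V, V), np.inf)
    np.fill_diagonal(L, 0.0)
    ii, jj = np.nonzero(mask)
    L[ii, jj] = 1.0 / (weights[ii, jj] + EDGE_LENGTH_EPS)
    return L


def floyd_warshall(L: np.ndarray) -> np.ndarray:
    D = L.copy()
    V = D.shape[0]
    for k in range(V):
        D = np.minimum(D, D[:, k:k + 1] + D[k:k + 1, :])
    return D


def closeness_oracle(weights: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Wasserman-Faust corrected closeness from the full distance matrix."""
    D = floyd_warshall(length_matrix(weights, mask))
    V = D.shape[0]
    c = np.zeros(V)
    for i in range(V):
        reach = np.isfinite(D[i])
        reach[i] = False
        r = int(reach.sum())
        if r:
            c[i] = (r / D[i, reach].sum()) * (r / (V - 1))
    return c


def betweenness_oracle(weights: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Brandes' algorithm with explicit Dijkstra, fractional path counts,
    normalized by (V-1)(V-2)/2."""
    V = weights.shape[0]
    L = length_matrix(weights, mask)
    bc = np.zeros(V)
    if V < 3:
        return bc
    for s in range(V):
        dist = np.full(V, np.inf)
        dist[s] = 0.0
        sigma = np.zeros(V)
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(V)]
        visited = np.zeros(V, dtype=bool)
        order = []
        for _ in range(V):
            cand = np.where(~visited, dist, np.inf)
            u = int(np.argmin(cand))
            if not np.isfinite(cand[u]):
                break
            visited[u] = True
            order.append(u)
            for v in range(V):
                if not np.isfinite(L[u, v]) or v == u:
                    continue
                alt = dist[u] + L[u, v]
                if alt < dist[v] - 1e-15:
                    dist[v] = alt
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                elif abs(alt - dist[v]) <= 1e-15 and u not in preds[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(V)
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each undirected pair counted from both endpoints -> halve
    return bc / 2.0 / ((V - 1) * (V - 2) / 2.0)


def bottleneck_scan_oracle(weights: np.ndarray) -> float:
    """Largest significance threshold keeping |w-0.5|-filtered graph connected."""
    V = weights.shape[0]
    sig = np.abs(weights - 0.5)
    iu, ju = np.triu_indices(V, k=1)
    for t in np.unique(sig[iu, ju])[::-1]:
        adj = sig >= t
        np.fill_diagonal(adj, False)
        if _connected(adj):
            return float(t)
    return 0.0


def _connected(adj: np.ndarray) -> bool:
    V = adj.shape[0]
    seen = {0}
    frontier = [0]
    while frontier:
        u = frontier.pop()
        for v in np.nonzero(adj[u])[0]:
            if v not in seen:
                seen.add(int(v))
                frontier.append(int(v))
    return len(seen) == V


def random_complete_graph(rng: np.random.Generator, n_nodes: int):
    """Symmetric weight matrix with entries in [0, 1], zero diagonal."""
    W = rng.random((n_nodes, n_nodes))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W
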