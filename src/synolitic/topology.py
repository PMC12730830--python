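"""Graph sparsification and structural node descriptors.

Edge *significance* is the deviation |w - 0.5| of the calibrated edge weight
from the neutral value: an edge whose pair classifier outputs 0.5 carries no
information and is the first to be pruned.  Three strategies are supported:

``none``
    keep the complete graph;
``threshold``
    keep exactly ceil(p * |E|) edges with the largest significance;
``min_connected``
    keep all edges with significance >= eps*, where eps* is the largest
    threshold for which the graph stays connected (found by binary search,
    then snapped to an actual edge significance so the bound is attained).

After sparsification each node i is described by the vector
f_i = [s_i, d_i, st_i, c_i, b_i]: raw concentration, normalized degree,
normalized strength, closeness and betweenness centrality.  Centralities are
computed on the weighted graph with the affinity-to-distance transform
length = 1 / (w + 1e-6), so high-confidence edges are short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy.sparse.csgraph import connected_components

from .graphs import SampleGraph

EDGE_LENGTH_EPS = 1e-6

SPARSIFIER_MODES = ("none", "threshold", "min_connected")


@dataclass
class SparsifierSpec:
    """Sparsification strategy and its parameters.

    ``p`` (threshold mode) is the retained fraction of edges in (0, 1];
    ``tol``/``max_iter`` bound the binary search of min_connected mode.
    """

    mode: str = "none"
    p: float | None = None
    tol: float = 1e-9
    max_iter: int = 60

    def __post_init__(self):
        if self.mode not in SPARSIFIER_MODES:
            raise ValueError(f"unknown sparsifier mode {self.mode!r}")
        if self.mode == "threshold":
            if self.p is None or not (0.0 < self.p <= 1.0):
                raise ValueError("threshold mode requires p in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def label(self) -> str:
        if self.mode == "threshold":
            return f"p={self.p:g}"
        return {"none": "none", "min_connected": "min_conn"}[self.mode]


def _significance(graph: SampleGraph) -> np.ndarray:
    return np.abs(graph.weights - 0.5)


def _require_complete(graph: SampleGraph) -> None:
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    V = graph.n_nodes
    if graph.n_edges != V * (V - 1) // 2:
        raise ValueError("sparsification expects a complete input graph")


def _is_connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def min_connected_threshold(graph: SampleGraph, tol: float = 1e-9,
                            max_iter: int = 60) -> float:
    """Largest significance threshold eps* that keeps the graph connected.

    Binary search on [0, max significance]; the converged interval is then
    snapped to an actual edge significance, so the returned value is exact
    (edges with |w-0.5| >= eps* form a connected spanning subgraph and any
    strictly larger edge-value threshold disconnects it).
    """
    _require_complete(graph)
    V = graph.n_nodes
    if V < 2:
        raise ValueError("need at least 2 nodes")
    S = _significance(graph)
    np.fill_diagonal(S, -1.0)

    def connected(eps: float) -> bool:
        return _is_connected(S >= eps)

    hi = float(S.max())
    if connected(hi):
        return hi
    lo = 0.0
    for _ in range(max_iter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        if connected(mid):
            lo = mid
        else:
            hi = mid
    # snap to the largest actual edge significance that keeps connectivity
    iu, ju = np.triu_indices(V, k=1)
    vals = np.unique(S[iu, ju])
    window = vals[(vals >= lo - tol) & (vals <= hi + tol)][::-1]
    for v in window:
        if connected(float(v)):
            return float(v)
    return lo


def bottleneck_threshold_bruteforce(graph: SampleGraph) -> float:
    """Exhaustive oracle for :func:`min_connected_threshold` (small graphs).

    Scans candidate thresholds (the sorted unique significances, descending)
    and returns the largest one that leaves the graph connected.
    """
    _require_complete(graph)
    V = graph.n_nodes
    S = _significance(graph)
    np.fill_diagonal(S, -1.0)
    iu, ju = np.triu_indices(V, k=1)
    for v in np.unique(S[iu, ju])[::-1]:
        if _is_connected(S >= v):
            return float(v)
    return 0.0


def sparsify(graph: SampleGraph, spec: SparsifierSpec) -> SampleGraph:
    """Apply a sparsification strategy; returns a new graph, input untouched."""
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    out = graph.copy()
    if spec.mode == "none":
        return out
    _require_complete(graph)
    V = graph.n_nodes
    S = _significance(graph)
    iu, ju = np.triu_indices(V, k=1)
    sig = S[iu, ju]
    mask = np.zeros((V, V), dtype=bool)
    if spec.mode == "threshold":
        n_keep = math.ceil(spec.p * len(sig))
        # sort by (-significance, i, j): deterministic lexicographic tie-break
        order = np.lexsort((ju, iu, -sig))
        keep = order[:n_keep]
        mask[iu[keep], ju[keep]] = True
    else:  # min_connected
        eps = min_connected_threshold(graph, tol=spec.tol, max_iter=spec.max_iter)
        keep = sig >= eps
        mask[iu[keep], ju[keep]] = True
    mask |= mask.T
    out.edge_mask = mask
    out.node_features = None  # stale after topology change
    return out


def compute_node_features(graph: SampleGraph,
                          raw_signal: np.ndarray | None = None) -> SampleGraph:
    """Fill the 5-column node-descriptor matrix [s, d, st, c, b].

    Must be called after any sparsification: descriptors reflect the final
    topology.  Degree and strength are normalized by |V|-1; betweenness by
    (|V|-1)(|V|-2)/2; closeness uses the per-component correction
    c_i = (R_i / sum of distances) * (R_i / (|V|-1)) with R_i the number of
    nodes reachable from i (isolated node: c_i = 0).
    """
    out = graph.copy()
    V = out.n_nodes
    s = np.asarray(raw_signal, dtype=float) if raw_signal is not None else out.raw_signal
    if s.shape != (V,):
        raise ValueError(f"raw_signal must have shape ({V},)")
    mask = np.triu(out.edge_mask, 1)
    Wm = out.masked_weights()
    denom = max(V - 1, 1)
    d = out.edge_mask.sum(axis=1) / denom
    st = Wm.sum(axis=1) / denom

    ii, jj = np.nonzero(mask)
    lengths = 1.0 / (out.weights[ii, jj] + EDGE_LENGTH_EPS)
    g = ig.Graph(n=V, edges=list(zip(ii.tolist(), jj.tolist())))
    if len(ii):
        dist = np.asarray(g.distances(weights=lengths.tolist()), dtype=float)
    else:
        dist = np.full((V, V), np.inf)
        np.fill_diagonal(dist, 0.0)

    c = np.zeros(V)
    for i in range(V):
        finite = np.isfinite(dist[i])
        finite[i] = False
        r = int(finite.sum())
        if r > 0:
            total = dist[i, finite].sum()
            c[i] = (r / total) * (r / denom)

    if V >= 3 and len(ii):
        raw_b = np.asarray(g.betweenness(weights=lengths.tolist(), directed=False))
        b = raw_b / ((V - 1) * (V - 2) / 2.0)
    else:
        b = np.zeros(V)

    out.node_features = np.column_stack([s, d, st, c, b])
    return out


def strip_node_features(graph: SampleGraph) -> SampleGraph:
    """Reduce node features to the single raw-signal column (ablation)."""
    out = graph.copy()
    out.node_features = out.raw_signal[:, None].copy()
    return out
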