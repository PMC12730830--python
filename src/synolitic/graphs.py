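"""Per-sample weighted graphs and their on-disk bundle format.

Each sample of a cohort becomes one :class:`SampleGraph`: analytes are nodes,
and every unordered analyte pair carries an edge weight in [0, 1] produced by
that pair's base classifier evaluated on the sample (0.5 = uninformative).
Graphs start complete; sparsification only flips entries of ``edge_mask``.

A *bundle* is a single ``.npz`` file holding all graphs of a cohort plus the
fingerprint of the pair-classifier bank that produced them, so stale bundles
cannot silently be mixed with a different bank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

BUNDLE_VERSION = 1


class BundleError(RuntimeError):
    """Raised on bundle version or fingerprint mismatch."""


@dataclass
class SampleGraph:
    """One sample's synolitic network.

    ``weights`` is the symmetric edge-weight matrix (diagonal zero); the
    boolean ``edge_mask`` marks retained edges (initially all off-diagonal
    entries).  ``raw_signal`` keeps the sample's concentration vector so node
    descriptors can be recomputed after any sparsification.  ``node_features``
    is filled by the topology module: either the full 5-column descriptor
    [s, d, st, c, b] or the single raw-signal column for the ablation.
    """

    sample_id: str
    label: int
    feature_names: list[str]
    weights: np.ndarray
    raw_signal: np.ndarray
    edge_mask: np.ndarray = None
    node_features: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        V = self.weights.shape[0]
        if self.weights.shape != (V, V):
            raise ValueError("weights must be square")
        if self.edge_mask is None:
            self.edge_mask = ~np.eye(V, dtype=bool)
        self.edge_mask = np.asarray(self.edge_mask, dtype=bool)
        self.raw_signal = np.asarray(self.raw_signal, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.edge_mask, 1).sum())

    def masked_weights(self) -> np.ndarray:
        """Weight matrix with discarded edges zeroed."""
        return np.where(self.edge_mask, self.weights, 0.0)

    def copy(self) -> "SampleGraph":
        return SampleGraph(
            sample_id=self.sample_id,
            label=self.label,
            feature_names=list(self.feature_names),
            weights=self.weights.copy(),
            raw_signal=self.raw_signal.copy(),
            edge_mask=self.edge_mask.copy(),
            node_features=None if self.node_features is None else self.node_features.copy(),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, name in enumerate(self.feature_names):
            g.add_node(name, raw_signal=float(self.raw_signal[i]))
        V = self.n_nodes
        for i in range(V):
            for j in range(i + 1, V):
                if self.edge_mask[i, j]:
                    g.add_edge(self.feature_names[i], self.feature_names[j],
                               weight=float(self.weights[i, j]))
        return g


def save_graph_bundle(graphs: list[SampleGraph], path, fingerprint: str = "") -> None:
    """Write graphs to one ``.npz`` bundle; lossless (weights bit-identical)."""
    path = Path(path)
    n = len(graphs)
    header = {
        "version": BUNDLE_VERSION,
        "fingerprint": fingerprint,
        "n_graphs": n,
        "feature_names": graphs[0].feature_names if n else [],
        "sample_ids": [g.sample_id for g in graphs],
        "labels": [int(g.label) for g in graphs],
        "has_node_features": bool(n and graphs[0].node_features is not None),
    }
    arrays: dict[str, np.ndarray] = {"_header": np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8)}
    if n:
        arrays["weights"] = np.stack([g.weights for g in graphs])
        arrays["edge_mask"] = np.stack([g.edge_mask for g in graphs])
        arrays["raw_signal"] = np.stack([g.raw_signal for g in graphs])
        if header["has_node_features"]:
            widths = {g.node_features.shape[1] if g.node_features is not None else -1
                      for g in graphs}
            if len(widths) != 1 or -1 in widths:
                raise BundleError("graphs must all carry node features of one width")
            arrays["node_features"] = np.stack([g.node_features for g in graphs])
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_graph_bundle(path, expect_fingerprint: str | None = None) -> list[SampleGraph]:
    """Read a bundle; raises :class:`BundleError` on fingerprint mismatch."""
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["_header"]).decode("utf-8"))
        if header["version"] != BUNDLE_VERSION:
            raise BundleError(f"unsupported bundle version {header['version']}")
        if expect_fingerprint is not None and header["fingerprint"] != expect_fingerprint:
            raise BundleError(
                f"bundle fingerprint {header['fingerprint']!r} does not match "
                f"expected {expect_fingerprint!r}")
        graphs = []
        for k in range(header["n_graphs"]):
            graphs.append(SampleGraph(
                sample_id=header["sample_ids"][k],
                label=header["labels"][k],
                feature_names=list(header["feature_names"]),
                weights=data["weights"][k],
                raw_signal=data["raw_signal"][k],
                edge_mask=data["edge_mask"][k],
                node_features=(data["node_features"][k]
                               if header["has_node_features"] else None),
            ))
    return graphs


def bundle_fingerprint(path) -> str:
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["_header"]).decode("utf-8"))
    return header["fingerprint"]
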