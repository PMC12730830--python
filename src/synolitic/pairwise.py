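"""Pair-classifier bank: the synolitic edge-weight construction.

For every unordered analyte pair (i, j) a linear soft-margin SVM is trained on
just those two (z-scored) features to separate cases from controls in the
training partition.  Its decision value is mapped to [0, 1] by Platt sigmoid
calibration, and that calibrated score, evaluated on one sample's pair of
concentrations, is the weight w_ij of the edge (i, j) in that sample's graph.
An edge weight near 0.5 means the pair carries no joint discriminative
information for this sample; deviations toward 0 or 1 encode antagonistic or
synergistic predictive power of the pair.

All pair models share the same per-feature standardization, fitted on the
training partition only, so held-out samples never influence edge weights.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.special import expit
from sklearn.svm import LinearSVC

from ._log import stage, timed_stage
from .cohort import OmicsDataset
from .graphs import SampleGraph


@dataclass
class PairwiseModelBank:
    """All C(p, 2) fitted and calibrated two-feature pair classifiers.

    Pair models are stored columnarly so a whole sample can be scored into its
    edge-weight matrix with a handful of vectorized operations.  For pair k
    with feature indices (i, j) = (pair_i[k], pair_j[k]) the edge weight of a
    sample with standardized values (z_i, z_j) is::

        f = coef[k, 0] * z_i + coef[k, 1] * z_j + intercept[k]
        w = expit(-(cal_a[k] * f + cal_b[k]))

    which covers Platt calibration (fitted cal_a < 0), the plain sigmoid
    fallback (cal_a = -1, cal_b = 0) and the neutral constant-0.5 model for
    degenerate pairs (cal_a = cal_b = 0).
    """

    feature_names: list[str]
    means: np.ndarray        # (p,) standardization location, training fold only
    scales: np.ndarray       # (p,) standardization scale, training fold only
    pair_i: np.ndarray       # (n_pairs,) first feature index, i < j
    pair_j: np.ndarray       # (n_pairs,)
    coef: np.ndarray         # (n_pairs, 2) linear SVM coefficients
    intercept: np.ndarray    # (n_pairs,)
    cal_a: np.ndarray        # (n_pairs,) calibration slope (<= 0)
    cal_b: np.ndarray        # (n_pairs,) calibration offset
    fingerprint: str = ""
    seed: int = 0
    svm_c: float = 1.0

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.scales


def _platt_calibrate(decision: np.ndarray, y: np.ndarray,
                     max_iter: int = 100, tol: float = 1e-10) -> tuple[float, float]:
    """Fit Platt's sigmoid P(y=1|f) = 1/(1+exp(a*f+b)) by regularized MLE.

    Newton's method with backtracking on the cross-entropy with Platt's
    smoothed targets (robust variant of Lin, Lin & Weng).  Deterministic.
    """
    f = np.asarray(decision, dtype=float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    t = np.where(y == 1, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))
    a, b = 0.0, np.log((n0 + 1.0) / (n1 + 1.0))

    def nll(a, b):
        z = a * f + b
        # cross-entropy of p = 1/(1+exp(z)) against targets t, stable form
        return float(np.sum(t * z + np.logaddexp(0.0, -z)))

    val = nll(a, b)
    for _ in range(max_iter):
        z = a * f + b
        p = expit(-z)                     # current P(y=1)
        d1 = t - p                        # dNLL/dz
        d2 = np.maximum(p * (1.0 - p), 1e-12)
        g_a, g_b = float(np.sum(d1 * f)), float(np.sum(d1))
        h_aa = float(np.sum(d2 * f * f)) + 1e-12
        h_ab = float(np.sum(d2 * f))
        h_bb = float(np.sum(d2)) + 1e-12
        det = h_aa * h_bb - h_ab * h_ab
        if det <= 0:
            break
        da = -(h_bb * g_a - h_ab * g_b) / det
        db = -(h_aa * g_b - h_ab * g_a) / det
        if abs(da) < tol and abs(db) < tol:
            break
        step = 1.0
        while step >= 1e-10:
            na, nb_ = a + step * da, b + step * db
            nval = nll(na, nb_)
            if nval < val + 1e-12:
                a, b, val = na, nb_, nval
                break
            step /= 2.0
        else:
            break
    return a, b


def fit_pairwise_bank(train: OmicsDataset, seed: int = 0, svm_c: float = 1.0,
                      min_calibration_class: int = 3) -> PairwiseModelBank:
    """Fit one calibrated linear-SVM pair model per unordered feature pair.

    Standardization and every pair model are functions of the training
    partition only.  A constant feature keeps scale 1 (with a warning); a pair
    whose two features are both constant becomes the neutral 0.5 edge.
    """
    classes = set(train.y.tolist())
    if classes != {0, 1}:
        raise ValueError(f"training data must contain both classes, got labels {sorted(classes)}")
    if min((train.y == 1).sum(), (train.y == 0).sum()) < 2:
        raise ValueError("need at least 2 training samples per class")

    X = np.asarray(train.X, dtype=float)
    p = train.n_features
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    constant = scales == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) in training data; scale set to 1",
            RuntimeWarning, stacklevel=2)
        scales = np.where(constant, 1.0, scales)
    Z = (X - means) / scales
    y = train.y

    iu, ju = np.triu_indices(p, k=1)
    n_pairs = len(iu)
    coef = np.zeros((n_pairs, 2))
    intercept = np.zeros(n_pairs)
    cal_a = np.zeros(n_pairs)
    cal_b = np.zeros(n_pairs)
    small_class = min((y == 1).sum(), (y == 0).sum()) < min_calibration_class

    with timed_stage("fit_pairwise_bank", n_pairs=n_pairs,
                     n_samples=train.n_samples, seed=seed):
        for k in range(n_pairs):
            i, j = iu[k], ju[k]
            if constant[i] and constant[j]:
                continue  # neutral edge: cal_a = cal_b = 0 -> w = 0.5
            clf = LinearSVC(C=svm_c, dual=False, tol=1e-6, max_iter=10_000)
            clf.fit(Z[:, [i, j]], y)
            coef[k] = clf.coef_[0]
            intercept[k] = clf.intercept_[0]
            f = Z[:, [i, j]] @ coef[k] + intercept[k]
            if small_class:
                cal_a[k], cal_b[k] = -1.0, 0.0
            else:
                a, b = _platt_calibrate(f, y)
                if a >= 0.0:
                    # non-monotone calibration would invert the score; fall
                    # back to the symmetric sigmoid squash of the decision value
                    a, b = -1.0, 0.0
                cal_a[k], cal_b[k] = a, b

    fp = hashlib.sha256(
        ("|".join(sorted(train.sample_ids)) + f"#seed={seed}#C={svm_c}#"
         + "|".join(train.feature_names)).encode("utf-8")).hexdigest()[:16]
    return PairwiseModelBank(
        feature_names=list(train.feature_names), means=means, scales=scales,
        pair_i=iu, pair_j=ju, coef=coef, intercept=intercept,
        cal_a=cal_a, cal_b=cal_b, fingerprint=fp, seed=seed, svm_c=svm_c)


def _pair_scores(bank: PairwiseModelBank, Z: np.ndarray) -> np.ndarray:
    """Calibrated scores for all pairs of all rows of standardized Z: (n, n_pairs)."""
    f = (Z[:, bank.pair_i] * bank.coef[:, 0]
         + Z[:, bank.pair_j] * bank.coef[:, 1]
         + bank.intercept)
    return expit(-(bank.cal_a * f + bank.cal_b))


def score_sample_edges(bank: PairwiseModelBank, sample_row: np.ndarray) -> np.ndarray:
    """Edge-weight matrix W (symmetric, entries in [0,1], zero diagonal)."""
    row = np.asarray(sample_row, dtype=float)
    if row.shape != (bank.n_features,):
        raise ValueError(
            f"sample has {row.shape} values, bank expects ({bank.n_features},)")
    if not np.all(np.isfinite(row)):
        raise ValueError("sample contains non-finite concentration values")
    z = bank.standardize(row[None, :])
    w = _pair_scores(bank, z)[0]
    W = np.zeros((bank.n_features, bank.n_features))
    W[bank.pair_i, bank.pair_j] = w
    W[bank.pair_j, bank.pair_i] = w
    return W


def build_sample_graphs(bank: PairwiseModelBank, ds: OmicsDataset) -> list[SampleGraph]:
    """One complete weighted :class:`SampleGraph` per sample of the cohort."""
    if list(ds.feature_names) != list(bank.feature_names):
        diff = set(ds.feature_names) ^ set(bank.feature_names)
        raise ValueError(f"feature names differ from bank's; symmetric difference: {sorted(diff)}")
    Z = bank.standardize(ds.X)
    if not np.all(np.isfinite(Z)):
        raise ValueError("cohort contains non-finite concentration values")
    scores = _pair_scores(bank, Z)
    p = bank.n_features
    graphs = []
    for s in range(ds.n_samples):
        W = np.zeros((p, p))
        W[bank.pair_i, bank.pair_j] = scores[s]
        W[bank.pair_j, bank.pair_i] = scores[s]
        graphs.append(SampleGraph(
            sample_id=ds.sample_ids[s], label=int(ds.y[s]),
            feature_names=list(bank.feature_names), weights=W,
            raw_signal=ds.X[s].copy()))
    stage("build_sample_graphs", n_graphs=len(graphs), n_nodes=p)
    return graphs


def rank_discriminative_pairs(graphs: list[SampleGraph], k: int
                              ) -> list[tuple[tuple[str, str], float]]:
    """Rank feature pairs by case-minus-control difference in mean edge weight.

    Returns the k pairs with the largest mean difference
    Δw(i,j) = mean over cases of w_ij − mean over controls of w_ij,
    sorted descending; ties broken lexicographically by pair name.
    """
    labels = np.array([g.label for g in graphs])
    if set(labels.tolist()) != {0, 1}:
        raise ValueError("graphs must contain both labels")
    Wc = np.mean([g.weights for g, l in zip(graphs, labels) if l == 1], axis=0)
    Wh = np.mean([g.weights for g, l in zip(graphs, labels) if l == 0], axis=0)
    delta = Wc - Wh
    names = graphs[0].feature_names
    p = len(names)
    iu, ju = np.triu_indices(p, k=1)
    n_pairs = len(iu)
    if k > n_pairs:
        warnings.warn(f"k={k} exceeds {n_pairs} pairs; returning all",
                      RuntimeWarning, stacklevel=2)
        k = n_pairs
    entries = [((names[i], names[j]), float(delta[i, j])) for i, j in zip(iu, ju)]
    entries.sort(key=lambda e: (-e[1], e[0][0], e[0][1]))
    return entries[:k]


def export_comparison_graph(ranked_pairs: list[tuple[tuple[str, str], float]],
                            hub_feature: str, path) -> nx.Graph:
    """Write the discriminative-pair comparison graph (GraphML + edge list).

    The exported edge set is the ranked pairs, with the case-vs-control mean
    weight difference stored as edge attribute ``delta_w``.  The hub analyte
    is always present as a node and flagged with a ``hub`` attribute.
    """
    if not ranked_pairs:
        raise ValueError("ranked_pairs must be non-empty")
    nodes = {n for (a, b), _ in ranked_pairs for n in (a, b)}
    if hub_feature not in nodes:
        # tolerate a hub that none of the top pairs touches, but it must at
        # least be a known analyte name to be meaningful
        warnings.warn(f"hub feature {hub_feature!r} has no edge among the "
                      "ranked pairs; added as an isolated node",
                      RuntimeWarning, stacklevel=2)
    g = nx.Graph()
    for (a, b), dw in ranked_pairs:
        g.add_edge(a, b, delta_w=float(dw))
    if hub_feature not in g:
        g.add_node(hub_feature)
    for n in g.nodes:
        g.nodes[n]["hub"] = n == hub_feature
    path = Path(path)
    nx.write_graphml(g, path)
    edge_list = path.with_suffix(".edges.tsv")
    with open(edge_list, "w") as fh:
        fh.write("source\ttarget\tdelta_w\n")
        for (a, b), dw in ranked_pairs:
            fh.write(f"{a}\t{b}\t{dw:.6f}\n")
    stage("export_comparison_graph", n_edges=g.number_of_edges(), hub=hub_feature)
    return g
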