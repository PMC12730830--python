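"""Pair-classifier bank: fitting, calibration, scoring and pair ranking."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from synolitic import (
    CohortSpec,
    build_sample_graphs,
    export_comparison_graph,
    fit_pairwise_bank,
    generate_cohort,
    rank_discriminative_pairs,
    score_sample_edges,
)
from synolitic.cohort import OmicsDataset
from synolitic.pairwise import _pair_scores

from conftest import make_graph


def _toy_dataset(X, y, visit="final"):
    n, p = X.shape
    return OmicsDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        patient_ids=[f"p{i}" for i in range(n)],
        X=X, feature_names=[f"f{j}" for j in range(p)],
        y=np.asarray(y), visit=[visit] * n)


class TestFitBank:
    def test_bank_size_is_choose_two(self, rng):
        for p, expected in [(3, 3), (8, 28)]:
            X = np.abs(rng.normal(5, 1, size=(12, p)))
            y = [0, 1] * 6
            bank = fit_pairwise_bank(_toy_dataset(X, y), seed=0)
            assert bank.n_pairs == expected

    def test_separable_pair_scores_cross_half(self, rng):
        # class 1 shifted far from class 0 in the (f0, f1) plane
        n = 10
        X = np.abs(rng.normal(5, 0.3, size=(2 * n, 3)))
        X[n:, 0] += 10
        X[n:, 1] += 10
        y = [0] * n + [1] * n
        ds = _toy_dataset(X, y)
        bank = fit_pairwise_bank(ds, seed=0)
        scores = _pair_scores(bank, bank.standardize(X))
        # pair (f0, f1) is pair index 0
        assert np.all(scores[n:, 0] > 0.5)
        assert np.all(scores[:n, 0] < 0.5)

    def test_bank_is_deterministic(self, small_cohort, rng):
        from synolitic import split_by_visit
        final, _ = split_by_visit(small_cohort)
        b1 = fit_pairwise_bank(final, seed=7)
        b2 = fit_pairwise_bank(final, seed=7)
        probe = np.abs(rng.normal(10, 3, size=final.n_features))
        assert b1.fingerprint == b2.fingerprint
        assert np.array_equal(score_sample_edges(b1, probe),
                              score_sample_edges(b2, probe))

    def test_single_class_training_rejected(self, rng):
        X = np.abs(rng.normal(5, 1, size=(6, 3)))
        ds = _toy_dataset(X, [1] * 6)
        with pytest.raises(ValueError, match="both classes"):
            fit_pairwise_bank(ds, seed=0)

    def test_constant_feature_warns_and_neutral_pair(self, rng):
        X = np.abs(rng.normal(5, 1, size=(10, 3)))
        X[:, 0] = 2.0
        X[:, 1] = 3.0
        ds = _toy_dataset(X, [0, 1] * 5)
        with pytest.warns(RuntimeWarning, match="constant"):
            bank = fit_pairwise_bank(ds, seed=0)
        w = score_sample_edges(bank, X[0])
        assert w[0, 1] == 0.5  # both-constant pair is the neutral edge

    def test_calibration_is_monotone_decreasing_slope(self, small_graphs, small_cohort):
        from synolitic import split_by_visit
        final, _ = split_by_visit(small_cohort)
        bank = fit_pairwise_bank(final, seed=42)
        assert np.all(bank.cal_a <= 0.0)

    def test_tiny_class_falls_back_to_sigmoid(self, rng):
        X = np.abs(rng.normal(5, 1, size=(6, 2)))
        ds = _toy_dataset(X, [0, 0, 0, 0, 1, 1])
        bank = fit_pairwise_bank(ds, seed=0)
        assert bank.cal_a[0] == -1.0 and bank.cal_b[0] == 0.0
        # a point exactly on the decision boundary scores 0.5
        a, b = bank.coef[0], bank.intercept[0]
        z_bound = np.array([1.0, -(a[0] * 1.0 + b) / a[1]])
        x_bound = z_bound * bank.scales + bank.means
        assert score_sample_edges(bank, x_bound)[0, 1] == pytest.approx(0.5, abs=1e-12)


class TestScoring:
    def test_weight_matrix_contract(self, small_graphs):
        for g in small_graphs[:5]:
            W = g.weights
            assert np.array_equal(W, W.T)
            assert np.all(np.diag(W) == 0)
            assert W.min() >= 0.0 and W.max() <= 1.0
            assert g.n_edges == g.n_nodes * (g.n_nodes - 1) // 2

    def test_identical_rows_identical_matrices(self, small_cohort):
        from synolitic import split_by_visit
        final, _ = split_by_visit(small_cohort)
        bank = fit_pairwise_bank(final, seed=1)
        row = final.X[0]
        assert np.array_equal(score_sample_edges(bank, row),
                              score_sample_edges(bank, row))

    def test_non_finite_input_rejected(self, small_cohort):
        from synolitic import split_by_visit
        final, _ = split_by_visit(small_cohort)
        bank = fit_pairwise_bank(final, seed=1)
        row = final.X[0].copy()
        row[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            score_sample_edges(bank, row)

    def test_feature_mismatch_lists_difference(self, small_cohort):
        from synolitic import split_by_visit
        final, _ = split_by_visit(small_cohort)
        bank = fit_pairwise_bank(final, seed=1)
        other = _toy_dataset(final.X[:, :4], final.y[:4].tolist() + [0] * 0)
        other = _toy_dataset(final.X[:4, :4], final.y[:4])
        with pytest.raises(ValueError, match="symmetric difference"):
            build_sample_graphs(bank, other)

    def test_scale_invariance_through_standardization(self, rng):
        X = np.abs(rng.normal(5, 1, size=(20, 4)))
        y = (rng.random(20) < 0.5).astype(int)
        y[:2] = [0, 1]
        b1 = fit_pairwise_bank(_toy_dataset(X, y), seed=0)
        b2 = fit_pairwise_bank(_toy_dataset(X * 10.0, y), seed=0)
        w1 = score_sample_edges(b1, X[0])
        w2 = score_sample_edges(b2, X[0] * 10.0)
        assert np.allclose(w1, w2, atol=1e-9)


class TestRanking:
    def _graphs_with_fixed_weights(self, case_means, ctrl_means, n_each=4):
        # 3 features; pairs in index order: (f0,f1)=AB, (f0,f2)=AC, (f1,f2)=BC
        graphs = []
        for k in range(n_each):
            for label, means in ((1, case_means), (0, ctrl_means)):
                W = np.zeros((3, 3))
                W[0, 1] = W[1, 0] = means[0]
                W[0, 2] = W[2, 0] = means[1]
                W[1, 2] = W[2, 1] = means[2]
                graphs.append(make_graph(W, label=label, sample_id=f"{label}_{k}"))
        return graphs

    def test_toy_ranking_matches_arithmetic(self):
        graphs = self._graphs_with_fixed_weights([0.9, 0.6, 0.5], [0.2, 0.5, 0.5])
        ranked = rank_discriminative_pairs(graphs, 3)
        assert [r[0] for r in ranked] == [("f0", "f1"), ("f0", "f2"), ("f1", "f2")]
        assert [round(r[1], 10) for r in ranked] == [0.7, 0.1, 0.0]

    def test_all_zero_differences_tie_break_lexicographic(self):
        graphs = self._graphs_with_fixed_weights([0.4, 0.4, 0.4], [0.4, 0.4, 0.4])
        ranked = rank_discriminative_pairs(graphs, 3)
        assert [r[0] for r in ranked] == [("f0", "f1"), ("f0", "f2"), ("f1", "f2")]
        assert all(r[1] == 0.0 for r in ranked)

    def test_k_too_large_warns_and_returns_all(self):
        graphs = self._graphs_with_fixed_weights([0.9, 0.6, 0.5], [0.2, 0.5, 0.5])
        with pytest.warns(RuntimeWarning, match="exceeds"):
            ranked = rank_discriminative_pairs(graphs, 99)
        assert len(ranked) == 3

    def test_single_label_rejected(self):
        graphs = self._graphs_with_fixed_weights([0.9, 0.6, 0.5], [0.2, 0.5, 0.5])
        only_cases = [g for g in graphs if g.label == 1]
        with pytest.raises(ValueError, match="both labels"):
            rank_discriminative_pairs(only_cases, 2)


class TestExport:
    def test_graphml_roundtrip_and_edge_attrs(self, tmp_path):
        ranked = [(("A", "B"), 0.712345), (("B", "C"), -0.05)]
        path = tmp_path / "cmp.graphml"
        export_comparison_graph(ranked, "B", path)
        g = nx.read_graphml(path)
        assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"}),
                                                frozenset({"B", "C"})}
        assert g.edges["A", "B"]["delta_w"] == pytest.approx(0.712345)
        assert g.nodes["B"]["hub"] is True
        # edge-list sidecar reproduces delta_w to 6 decimals
        lines = (tmp_path / "cmp.edges.tsv").read_text().strip().splitlines()
        assert lines[1].split("\t") == ["A", "B", "0.712345"]

    def test_single_pair_export(self, tmp_path):
        export_comparison_graph([(("X", "Y"), 0.3)], "X", tmp_path / "g.graphml")
        g = nx.read_graphml(tmp_path / "g.graphml")
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_empty_ranking_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="non-empty"):
            export_comparison_graph([], "A", tmp_path / "g.graphml")


class TestSignalProperties:
    def test_null_pair_aucs_centred_at_half(self):
        # no-signal cohort: training-set pair AUCs should average ~0.5
        spec = CohortSpec(n_cases=200, n_controls=200, n_features=35,
                          n_signal_pairs=0, n_marginal_markers=0,
                          include_penultimate=False, seed=77)
        ds = generate_cohort(spec)
        bank = fit_pairwise_bank(ds, seed=77)
        scores = _pair_scores(bank, bank.standardize(ds.X))
        aucs = np.array([roc_auc_score(ds.y, scores[:, k])
                         for k in range(bank.n_pairs)])
        assert bank.n_pairs >= 500
        assert abs(aucs.mean() - 0.5) < 0.05

    def test_planted_pair_beats_null_distribution(self):
        # one strongly planted pair; held-out AUC above the null 95th pct
        spec = CohortSpec(n_cases=1000, n_controls=1000, n_features=30,
                          n_signal_pairs=1, n_marginal_markers=0,
                          pair_effect=0.9, include_penultimate=False, seed=5)
        train = generate_cohort(spec)
        test = generate_cohort(
            CohortSpec(**{**spec.__dict__, "seed": 6}))
        bank = fit_pairwise_bank(train, seed=5)
        scores = _pair_scores(bank, bank.standardize(test.X))
        aucs = np.array([roc_auc_score(test.y, scores[:, k])
                         for k in range(bank.n_pairs)])
        signal_idx = 0  # pair (f0, f1) is the planted one and pair index 0
        null_aucs = np.delete(aucs, signal_idx)
        assert aucs[signal_idx] > np.percentile(null_aucs, 95)
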