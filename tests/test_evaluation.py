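"""Cross-validation protocol, threshold selection, metrics, baselines."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from synolitic import (
    CohortSpec,
    ExperimentConfig,
    GNNConfig,
    SparsifierSpec,
    compute_metrics,
    fit_baseline,
    generate_cohort,
    make_cv_plan,
    run_experiment,
    run_training_fraction_sweep,
    select_threshold,
    split_by_visit,
)


@pytest.fixture(scope="module")
def study_shape_cohort():
    return generate_cohort(CohortSpec(n_cases=28, n_controls=36, n_features=8,
                                      n_signal_pairs=2, n_marginal_markers=1,
                                      seed=17))


class TestCVPlan:
    def test_fold_sizes_for_64_samples(self, study_shape_cohort):
        plan = make_cv_plan(study_shape_cohort, k=5, seed=0)
        sizes = sorted(len(f.test_ids) for f in plan.folds)
        assert sizes == [12, 13, 13, 13, 13]

    def test_patients_never_straddle_train_and_test(self, study_shape_cohort):
        final, _ = split_by_visit(study_shape_cohort)
        pat = dict(zip(final.sample_ids, final.patient_ids))
        plan = make_cv_plan(study_shape_cohort, k=5, seed=0)
        for fold in plan.folds:
            train_p = {pat[s] for s in fold.train_ids}
            test_p = {pat[s] for s in fold.test_ids}
            assert train_p.isdisjoint(test_p)

    def test_holdout_patients_subset_of_test_patients(self, study_shape_cohort):
        _, pen = split_by_visit(study_shape_cohort)
        final, _ = split_by_visit(study_shape_cohort)
        pat_final = dict(zip(final.sample_ids, final.patient_ids))
        pat_pen = dict(zip(pen.sample_ids, pen.patient_ids))
        plan = make_cv_plan(study_shape_cohort, k=5, seed=0)
        for fold in plan.folds:
            hold_p = {pat_pen[s] for s in fold.holdout_ids}
            test_p = {pat_final[s] for s in fold.test_ids}
            assert hold_p <= test_p

    def test_folds_partition_final_samples(self, study_shape_cohort):
        final, _ = split_by_visit(study_shape_cohort)
        plan = make_cv_plan(study_shape_cohort, k=5, seed=0)
        all_test = [s for f in plan.folds for s in f.test_ids]
        assert sorted(all_test) == sorted(final.sample_ids)

    def test_stratification_within_one_sample(self, study_shape_cohort):
        final, _ = split_by_visit(study_shape_cohort)
        label = dict(zip(final.sample_ids, final.y))
        plan = make_cv_plan(study_shape_cohort, k=5, seed=0)
        global_rate = np.mean(final.y)
        for fold in plan.folds:
            n_case = sum(label[s] for s in fold.test_ids)
            expected = global_rate * len(fold.test_ids)
            assert abs(n_case - expected) <= 1.0

    def test_seeded_determinism(self, study_shape_cohort):
        p1 = make_cv_plan(study_shape_cohort, k=5, seed=3)
        p2 = make_cv_plan(study_shape_cohort, k=5, seed=3)
        p3 = make_cv_plan(study_shape_cohort, k=5, seed=4)
        assert [f.test_ids for f in p1.folds] == [f.test_ids for f in p2.folds]
        assert [f.test_ids for f in p1.folds] != [f.test_ids for f in p3.folds]

    def test_k_exceeding_class_count_rejected(self):
        ds = generate_cohort(CohortSpec(n_cases=3, n_controls=10, n_features=6,
                                        n_signal_pairs=1, n_marginal_markers=0,
                                        seed=0))
        with pytest.raises(ValueError, match="class 1"):
            make_cv_plan(ds, k=5, seed=0)


class TestThreshold:
    def test_midpoint_of_separating_gap(self):
        t = select_threshold(np.array([0.1, 0.4, 0.6, 0.9]),
                             np.array([0, 0, 1, 1]))
        assert t == pytest.approx(0.5)

    def test_inverted_classifier_still_returns_threshold(self):
        t = select_threshold(np.array([0.9, 0.8, 0.2, 0.1]),
                             np.array([0, 0, 1, 1]))
        assert 0.0 < t < 1.0

    def test_all_positive_labels_predicts_everything_positive(self):
        probs = np.array([0.3, 0.5, 0.7])
        t = select_threshold(probs, np.array([1, 1, 1]))
        assert t < probs.min()

    def test_constant_probabilities_warn_and_default(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            t = select_threshold(np.full(4, 0.6), np.array([0, 1, 0, 1]))
        assert t == 0.5


class TestMetrics:
    def test_perfect_classifier_scores_100(self):
        m = compute_metrics(np.array([0., 0., 1., 1.]),
                            np.array([0, 0, 1, 1]), 0.5)
        assert all(m[k] == 100.0 for k in m)

    def test_predict_all_positive_regime(self):
        probs = np.full(10, 0.9)
        labels = np.array([1] * 6 + [0] * 4)
        m = compute_metrics(probs, labels, 0.5)
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 0.0

    def test_worked_confusion_example(self):
        # TP=9 FN=1 TN=3 FP=7 at threshold 0.5
        probs = np.array([0.9] * 9 + [0.1] * 1 + [0.1] * 3 + [0.9] * 7)
        labels = np.array([1] * 10 + [0] * 10)
        m = compute_metrics(probs, labels, 0.5)
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(30.0)
        assert m["f1"] == pytest.approx(69.23, abs=0.005)

    def test_f1_identity_confusion_vs_precision_recall(self, rng):
        for _ in range(20):
            probs = rng.random(30)
            labels = (rng.random(30) < 0.4).astype(int)
            if labels.sum() in (0, 30):
                continue
            m = compute_metrics(probs, labels, 0.5)
            preds = (probs >= 0.5).astype(int)
            tp = np.sum((preds == 1) & (labels == 1))
            fp = np.sum((preds == 1) & (labels == 0))
            fn = np.sum((preds == 0) & (labels == 1))
            f1_counts = 100.0 * 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else 0.0
            assert abs(m["f1"] - f1_counts) < 1e-12

    def test_auc_equals_normalized_mann_whitney(self, rng):
        probs = rng.random(40)  # tie-free with probability 1
        labels = np.array([1] * 15 + [0] * 25)
        m = compute_metrics(probs, labels, 0.5)
        u, _ = mannwhitneyu(probs[labels == 1], probs[labels == 0])
        assert m["roc_auc"] == pytest.approx(100.0 * u / (15 * 25), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(np.array([]), np.array([]), 0.5)


class TestBaselines:
    @pytest.mark.parametrize("name", ["xgboost", "random_forest", "svm",
                                      "logistic_regression", "elastic_net"])
    def test_interface_contract(self, name, rng):
        X = rng.normal(size=(20, 10))
        y = np.array([0, 1] * 10)
        clf = fit_baseline(name, X, y, seed=0)
        p = clf.predict_proba(X)[:, 1]
        assert p.shape == (20,)
        assert np.all((p >= 0) & (p <= 1))

    def test_separable_logistic_reaches_auc_one(self, rng):
        X = rng.normal(size=(30, 5))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y == 1, 5.0, -5.0)
        clf = fit_baseline("logistic_regression", X, y, seed=0)
        assert roc_auc_score(y, clf.predict_proba(X)[:, 1]) == 1.0

    def test_seeded_determinism_of_stochastic_learners(self, rng):
        X = rng.normal(size=(40, 8))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        for name in ("xgboost", "random_forest"):
            p1 = fit_baseline(name, X, y, seed=5).predict_proba(X)[:, 1]
            p2 = fit_baseline(name, X, y, seed=5).predict_proba(X)[:, 1]
            assert np.array_equal(p1, p2)

    def test_unknown_name_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown baseline"):
            fit_baseline("deep_forest", np.zeros((4, 2)), np.array([0, 1, 0, 1]))


@pytest.fixture(scope="module")
def tiny_config():
    return ExperimentConfig(
        seed=29, k_folds=3, architectures=["GCN"],
        sparsifiers=[SparsifierSpec("threshold", p=0.5)],
        node_features=[True], baselines=["logistic_regression"],
        gnn=GNNConfig(hidden_size=16, max_epochs=15))


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(CohortSpec(n_cases=15, n_controls=15, n_features=8,
                                      n_signal_pairs=2, n_marginal_markers=1,
                                      seed=29))


class TestRunExperiment:
    def test_report_structure_and_ranges(self, tiny_cohort, tiny_config):
        rep = run_experiment(tiny_cohort, tiny_config)
        df = rep.records
        per_fold = df[df["fold"] != "pooled"]
        assert set(per_fold["model"]) == {"GCN", "logistic_regression"}
        assert set(per_fold["window"]) == {"primary", "holdout"}
        assert set(per_fold["metric"]) == {"roc_auc", "f1", "sensitivity",
                                           "specificity"}
        # 2 models x 2 windows x 4 metrics x 3 folds
        assert len(per_fold) == 2 * 2 * 4 * 3
        vals = per_fold["value"].dropna()
        assert vals.between(0, 100).all()
        assert not rep.aggregate().empty
        assert "GCN" in rep.summary_table()

    def test_pooled_auc_rows_present(self, tiny_cohort, tiny_config):
        rep = run_experiment(tiny_cohort, tiny_config)
        pooled = rep.records[rep.records["fold"] == "pooled"]
        assert len(pooled) == 4  # 2 models x 2 windows
        assert (pooled["metric"] == "roc_auc").all()

    def test_csv_roundtrip(self, tiny_cohort, tiny_config, tmp_path):
        import pandas as pd
        rep = run_experiment(tiny_cohort, tiny_config)
        rep.to_csv(tmp_path / "r.csv")
        back = pd.read_csv(tmp_path / "r.csv")
        assert len(back) == len(rep.records)

    def test_bank_fingerprint_depends_only_on_training_partition(self, tiny_cohort):
        from synolitic import fit_pairwise_bank
        final, _ = split_by_visit(tiny_cohort)
        plan = make_cv_plan(tiny_cohort, k=3, seed=29)
        tr = final.subset_by_sample_ids(plan.folds[0].train_ids)
        b1 = fit_pairwise_bank(tr, seed=29)
        b2 = fit_pairwise_bank(tr, seed=29)
        other = final.subset_by_sample_ids(plan.folds[1].train_ids)
        b3 = fit_pairwise_bank(other, seed=29)
        assert b1.fingerprint == b2.fingerprint
        assert b1.fingerprint != b3.fingerprint


class TestTrainingFractionSweep:
    def test_sweep_interface_and_consistency(self, tiny_cohort, tiny_config):
        df = run_training_fraction_sweep(tiny_cohort, [1.0, 0.6], tiny_config)
        assert list(df["fraction"]) == [1.0, 0.6]
        assert df["auc_sgnn"].between(0, 100).all()
        assert df["auc_baseline"].between(0, 100).all()
        # fraction 1.0 reproduces the grid cell (same seed, same pipeline)
        rep = run_experiment(tiny_cohort, tiny_config)
        cell = rep.cell_mean("GCN", "primary", "roc_auc")
        assert df.loc[df["fraction"] == 1.0, "auc_sgnn"].iloc[0] == \
            pytest.approx(cell, abs=1e-9)

    def test_too_small_fraction_skipped_with_warning(self, tiny_cohort, tiny_config):
        with pytest.warns(RuntimeWarning, match="skipped"):
            df = run_training_fraction_sweep(tiny_cohort, [0.05], tiny_config)
        assert df.empty

    def test_invalid_fraction_rejected(self, tiny_cohort, tiny_config):
        with pytest.raises(ValueError, match="fractions"):
            run_training_fraction_sweep(tiny_cohort, [1.5], tiny_config)
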