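"""Patient-level cross-validated benchmarking of graph and baseline models.

Protocol: patients (not samples) are partitioned into k stratified folds.
In each fold the held-out patients' final-visit samples form the *Primary
Test Set* (< 1 year pre-diagnosis window) and the penultimate samples of the
same patients form the *Early-Detection Holdout Set* (1-2 years window).
Everything fitted — the pair-classifier bank, feature standardization, the
model, and the decision threshold — is a function of the training-fold
samples only; the threshold (chosen to maximize F1 on a validation split of
the training fold) is reused unchanged on the holdout window.

Reported metrics (ROC-AUC, F1, sensitivity, specificity) are on the percent
scale, aggregated as mean +/- sd over folds; a pooled-predictions AUC row is
also emitted for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._log import stage, timed_stage
from .cohort import OmicsDataset, split_by_visit
from .config import ExperimentConfig
from .nn.training import fit_gnn, predict_proba
from .pairwise import build_sample_graphs, fit_pairwise_bank
from .topology import compute_node_features, sparsify, strip_node_features

_MOD = 2 ** 31 - 1


# ----------------------------------------------------------------------
# cross-validation plan
# ----------------------------------------------------------------------

@dataclass
class FoldPlan:
    train_ids: list[str]
    test_ids: list[str]
    holdout_ids: list[str]


@dataclass
class CVPlan:
    k: int
    seed: int
    folds: list[FoldPlan]


def make_cv_plan(ds: OmicsDataset, k: int = 5, seed: int = 0) -> CVPlan:
    """Stratified patient-level folds with paired early-detection holdouts."""
    final_ds, pen_ds = split_by_visit(ds)
    pen_patients = set(pen_ds.patient_ids)
    final_patients = set(final_ds.patient_ids)
    orphans = pen_patients - final_patients
    if orphans:
        raise ValueError(
            f"patient {sorted(orphans)[0]!r} has a penultimate but no final sample")
    patients = np.array(final_ds.patient_ids)
    labels = final_ds.y
    for cls in (0, 1):
        n_cls = int((labels == cls).sum())
        if k > n_cls:
            raise ValueError(f"k={k} exceeds the {n_cls} patients of class {cls}")
    pen_by_patient = dict(zip(pen_ds.patient_ids, pen_ds.sample_ids))

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr_idx, te_idx in skf.split(patients, labels):
        test_patients = patients[te_idx]
        folds.append(FoldPlan(
            train_ids=[final_ds.sample_ids[i] for i in tr_idx],
            test_ids=[final_ds.sample_ids[i] for i in te_idx],
            holdout_ids=[pen_by_patient[p] for p in test_patients
                         if p in pen_by_patient],
        ))
    return CVPlan(k=k, seed=seed, folds=folds)


# ----------------------------------------------------------------------
# threshold and metrics
# ----------------------------------------------------------------------

def _f1(preds: np.ndarray, labels: np.ndarray) -> float:
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2.0 * tp / (2 * tp + fp + fn)


def select_threshold(val_probs: np.ndarray, val_labels: np.ndarray) -> float:
    """F1-maximizing threshold over midpoints of sorted unique probabilities."""
    probs = np.asarray(val_probs, dtype=float)
    labels = np.asarray(val_labels, dtype=int)
    if probs.size == 0:
        raise ValueError("empty validation split")
    uniq = np.unique(probs)
    if len(uniq) == 1:
        warnings.warn("constant validation probabilities; threshold 0.5",
                      RuntimeWarning, stacklevel=2)
        return 0.5
    low = uniq[0] / 2.0 if uniq[0] > 0 else np.nextafter(0.0, 1.0)
    candidates = np.concatenate([[low], (uniq[:-1] + uniq[1:]) / 2.0])
    best_t, best_f1 = candidates[0], -1.0
    for t in candidates:
        f1 = _f1((probs >= t).astype(int), labels)
        if f1 > best_f1 + 1e-15:
            best_t, best_f1 = float(t), f1
    return best_t


def compute_metrics(probs: np.ndarray, labels: np.ndarray,
                    threshold: float) -> dict[str, float]:
    """ROC-AUC, F1, sensitivity, specificity on the percent scale.

    AUC is rank-based (equivalent to the normalized Mann-Whitney U
    statistic); if only one class is present it is reported as NaN.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size == 0:
        raise ValueError("empty input")
    preds = (probs >= threshold).astype(int)
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * prec * sens / (prec + sens)
          if (tp + fn) and (prec + sens) > 0 else 0.0)
    if len(set(labels.tolist())) == 2:
        auc = roc_auc_score(labels, probs)
    else:
        warnings.warn("single-class labels: ROC-AUC undefined",
                      RuntimeWarning, stacklevel=2)
        auc = np.nan
    return {"roc_auc": 100.0 * auc, "f1": 100.0 * f1,
            "sensitivity": 100.0 * sens, "specificity": 100.0 * spec}


# ----------------------------------------------------------------------
# baselines
# ----------------------------------------------------------------------

def fit_baseline(name: str, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one of the conventional classifiers on flat feature vectors.

    Library-default hyperparameters with a fixed seed; features are z-scored
    inside the pipeline so standardization is refitted per training fold.
    """
    if len(set(np.asarray(y).tolist())) < 2:
        raise ValueError("both classes required in training data")
    makers = {
        "xgboost": lambda: XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0),
        "random_forest": lambda: RandomForestClassifier(
            random_state=seed, n_jobs=1),
        "svm": lambda: CalibratedClassifierCV(SVC(random_state=seed),
                                              ensemble=False),
        "logistic_regression": lambda: LogisticRegression(max_iter=2000),
        "elastic_net": lambda: LogisticRegression(
            solver="saga", l1_ratio=0.5, max_iter=5000, random_state=seed),
    }
    if name not in makers:
        raise ValueError(f"unknown baseline {name!r}; choose from {sorted(makers)}")
    pipe = make_pipeline(StandardScaler(), makers[name]())
    pipe.fit(X, y)
    return pipe


# ----------------------------------------------------------------------
# experiment grid
# ----------------------------------------------------------------------

@dataclass
class EvalReport:
    """Tidy per-fold metrics plus helpers mirroring the benchmark tables."""

    records: pd.DataFrame
    config_snapshot: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        df = self.records[self.records["fold"] != "pooled"]
        g = df.groupby(["model", "sparsity", "node_features", "window", "metric"],
                       dropna=False)["value"]
        out = g.agg(["mean", "std"]).reset_index()
        out["std"] = out["std"].fillna(0.0)
        return out

    def cell_mean(self, model: str, window: str, metric: str = "roc_auc",
                  sparsity: str | None = None,
                  node_features: bool | None = None) -> float:
        df = self.records[(self.records["model"] == model)
                          & (self.records["window"] == window)
                          & (self.records["metric"] == metric)
                          & (self.records["fold"] != "pooled")]
        if sparsity is not None:
            df = df[df["sparsity"] == sparsity]
        if node_features is not None:
            df = df[df["node_features"] == str(node_features)]
        return float(df["value"].mean())

    def summary_table(self, metric: str = "roc_auc") -> str:
        """Formatted text table: one row per cell, 'mean ± sd / mean ± sd'
        for the primary and holdout windows."""
        agg = self.aggregate()
        agg = agg[agg["metric"] == metric]
        lines = [f"{'Model':<22}{'Sparsity':<12}{'NodeFeat':<10}"
                 f"{metric} (%)  primary / holdout"]
        cells = agg[["model", "sparsity", "node_features"]].drop_duplicates()
        for _, c in cells.iterrows():
            sub = agg[(agg["model"] == c["model"])
                      & (agg["sparsity"] == c["sparsity"])
                      & (agg["node_features"] == c["node_features"])]
            parts = []
            for window in ("primary", "holdout"):
                row = sub[sub["window"] == window]
                if len(row):
                    parts.append(f"{row['mean'].iloc[0]:.2f} ± {row['std'].iloc[0]:.2f}")
                else:
                    parts.append("-")
            lines.append(f"{c['model']:<22}{c['sparsity']:<12}"
                         f"{c['node_features']:<10}{parts[0]} / {parts[1]}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.records.to_csv(Path(path), index=False)


@dataclass
class _FoldData:
    train: OmicsDataset
    val: OmicsDataset
    test: OmicsDataset
    holdout: OmicsDataset | None


def _cell_seed(base: int, fold: int, cell: int) -> int:
    return (base * 1_000_003 + fold * 10_007 + cell * 101 + 12_345) % _MOD


def _prepare_fold(final_ds: OmicsDataset, pen_ds: OmicsDataset, fold: FoldPlan,
                  config: ExperimentConfig, fold_idx: int,
                  fraction: float = 1.0) -> _FoldData:
    tr = final_ds.subset_by_sample_ids(fold.train_ids)
    if fraction < 1.0:
        rng = np.random.default_rng((config.seed + 131 * fold_idx) % _MOD)
        keep: list[int] = []
        for cls in (0, 1):
            idx = np.flatnonzero(tr.y == cls)
            n_keep = max(int(round(fraction * len(idx))), 0)
            if n_keep < 2:
                raise ValueError(
                    f"fraction {fraction} leaves <2 samples of class {cls}")
            keep.extend(rng.choice(idx, size=n_keep, replace=False).tolist())
        tr = tr.subset(sorted(keep))
    sss = StratifiedShuffleSplit(n_splits=1, test_size=config.val_fraction,
                                 random_state=(config.seed + 977 * fold_idx) % _MOD)
    tr_idx, val_idx = next(sss.split(np.zeros(tr.n_samples), tr.y))
    test = final_ds.subset_by_sample_ids(fold.test_ids)
    holdout = (pen_ds.subset_by_sample_ids(fold.holdout_ids)
               if fold.holdout_ids else None)
    return _FoldData(train=tr.subset(sorted(tr_idx)),
                     val=tr.subset(sorted(val_idx)),
                     test=test, holdout=holdout)


def _eval_windows(probs_by_window, labels_by_window, threshold, records, pooled,
                  model, sparsity, node_features, fold_label):
    for window, probs in probs_by_window.items():
        labels = labels_by_window[window]
        met = compute_metrics(probs, labels, threshold)
        for metric, value in met.items():
            records.append({"model": model, "sparsity": sparsity,
                            "node_features": node_features, "window": window,
                            "fold": fold_label, "metric": metric,
                            "value": value, "threshold": threshold})
        key = (model, sparsity, node_features, window)
        pooled.setdefault(key, ([], []))
        pooled[key][0].extend(probs.tolist())
        pooled[key][1].extend(np.asarray(labels).tolist())


def run_experiment(ds: OmicsDataset, config: ExperimentConfig) -> EvalReport:
    """Run the full grid: GNN cells x sparsifiers x node-feature flag,
    plus the conventional baselines, under patient-level k-fold CV."""
    final_ds, pen_ds = split_by_visit(ds)
    plan = make_cv_plan(ds, k=config.k_folds, seed=config.seed)
    records: list[dict] = []
    pooled: dict = {}

    with timed_stage("run_experiment", n_samples=ds.n_samples,
                     n_features=ds.n_features, seed=config.seed):
        for f_idx, fold in enumerate(plan.folds):
            prep = _prepare_fold(final_ds, pen_ds, fold, config, f_idx)
            bank = fit_pairwise_bank(prep.train, seed=config.seed,
                                     svm_c=config.svm_c)
            splits = {"train": prep.train, "val": prep.val, "test": prep.test}
            if prep.holdout is not None:
                splits["holdout"] = prep.holdout
            base_graphs = {k: build_sample_graphs(bank, v)
                           for k, v in splits.items()}

            cell = 0
            for sp_spec in config.sparsifiers:
                sparse = {k: [sparsify(g, sp_spec) for g in v]
                          for k, v in base_graphs.items()}
                feats = {k: [compute_node_features(g) for g in v]
                         for k, v in sparse.items()}
                for nf in config.node_features:
                    use = feats if nf else {
                        k: [strip_node_features(g) for g in v]
                        for k, v in sparse.items()}
                    for arch in config.architectures:
                        gcfg = config.gnn.replace(
                            architecture=arch,
                            seed=_cell_seed(config.seed, f_idx, cell))
                        trained = fit_gnn(use["train"], use["val"], gcfg)
                        thr = select_threshold(
                            predict_proba(trained, use["val"]), prep.val.y)
                        probs_by = {"primary": predict_proba(trained, use["test"])}
                        labels_by = {"primary": prep.test.y}
                        if "holdout" in use:
                            probs_by["holdout"] = predict_proba(trained, use["holdout"])
                            labels_by["holdout"] = prep.holdout.y
                        _eval_windows(probs_by, labels_by, thr, records, pooled,
                                      arch, sp_spec.label(), str(nf), str(f_idx))
                        cell += 1

            for b_idx, name in enumerate(config.baselines):
                clf = fit_baseline(name, prep.train.X, prep.train.y,
                                   seed=_cell_seed(config.seed, f_idx, 1000 + b_idx))
                thr = select_threshold(clf.predict_proba(prep.val.X)[:, 1],
                                       prep.val.y)
                probs_by = {"primary": clf.predict_proba(prep.test.X)[:, 1]}
                labels_by = {"primary": prep.test.y}
                if prep.holdout is not None:
                    probs_by["holdout"] = clf.predict_proba(prep.holdout.X)[:, 1]
                    labels_by["holdout"] = prep.holdout.y
                _eval_windows(probs_by, labels_by, thr, records, pooled,
                              name, "-", "-", str(f_idx))

    # pooled-predictions AUC for transparency
    for (model, sparsity, nf, window), (probs, labels) in pooled.items():
        labels_arr = np.asarray(labels)
        if len(set(labels_arr.tolist())) == 2:
            records.append({"model": model, "sparsity": sparsity,
                            "node_features": nf, "window": window,
                            "fold": "pooled", "metric": "roc_auc",
                            "value": 100.0 * roc_auc_score(labels_arr, probs),
                            "threshold": np.nan})
    return EvalReport(records=pd.DataFrame.from_records(records),
                      config_snapshot=config.resolved())


def run_training_fraction_sweep(ds: OmicsDataset, fractions: list[float],
                                config: ExperimentConfig) -> pd.DataFrame:
    """Primary-test AUC of the first grid cell vs one baseline while the
    training side is stratified-subsampled to each fraction."""
    for frac in fractions:
        if not (0.0 < frac <= 1.0):
            raise ValueError("fractions must lie in (0, 1]")
    final_ds, pen_ds = split_by_visit(ds)
    plan = make_cv_plan(ds, k=config.k_folds, seed=config.seed)
    sp_spec = config.sparsifiers[0]
    nf = config.node_features[0]
    arch = config.architectures[0]
    baseline = config.baselines[0]
    rows = []
    for frac in fractions:
        gnn_aucs, base_aucs = [], []
        for f_idx, fold in enumerate(plan.folds):
            try:
                prep = _prepare_fold(final_ds, pen_ds, fold, config, f_idx,
                                     fraction=frac)
            except ValueError as err:
                warnings.warn(f"fraction {frac}, fold {f_idx} skipped: {err}",
                              RuntimeWarning, stacklevel=2)
                continue
            bank = fit_pairwise_bank(prep.train, seed=config.seed,
                                     svm_c=config.svm_c)
            graphs = {k: build_sample_graphs(bank, v) for k, v in
                      {"train": prep.train, "val": prep.val,
                       "test": prep.test}.items()}
            graphs = {k: [sparsify(g, sp_spec) for g in v]
                      for k, v in graphs.items()}
            if nf:
                graphs = {k: [compute_node_features(g) for g in v]
                          for k, v in graphs.items()}
            else:
                graphs = {k: [strip_node_features(g) for g in v]
                          for k, v in graphs.items()}
            gcfg = config.gnn.replace(architecture=arch,
                                      seed=_cell_seed(config.seed, f_idx, 0))
            trained = fit_gnn(graphs["train"], graphs["val"], gcfg)
            gnn_aucs.append(roc_auc_score(
                prep.test.y, predict_proba(trained, graphs["test"])))
            clf = fit_baseline(baseline, prep.train.X, prep.train.y,
                               seed=_cell_seed(config.seed, f_idx, 1000))
            base_aucs.append(roc_auc_score(
                prep.test.y, clf.predict_proba(prep.test.X)[:, 1]))
        if gnn_aucs:
            rows.append({"fraction": frac,
                         "auc_sgnn": 100.0 * float(np.mean(gnn_aucs)),
                         "auc_baseline": 100.0 * float(np.mean(base_aucs)),
                         "n_folds": len(gnn_aucs)})
    return pd.DataFrame(rows)
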