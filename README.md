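# synolitic

Sample-specific network representations ("synolitic networks") and graph
neural networks for classifying high-dimensional tabular omics cohorts —
built for the p ≫ n regime of serum-proteomics biomarker panels, where a
hundred analytes are measured on a few dozen pre-diagnostic samples and the
earliest disease signal is expected in the *rewiring of analyte–analyte
relationships* rather than in any single concentration.

## Who this is for

Computational biologists benchmarking network-based classifiers against
conventional ML on small case–control omics panels, particularly
longitudinal early-detection designs where each patient contributes a
final sample (< 1 year before diagnosis) and a penultimate sample
(1–2 years before), and the question is how much discriminative signal
survives at the earlier time point.

## The method

For a cohort with analytes 1..p, every unordered pair (i, j) gets its own
base classifier: a linear SVM trained on just those two z-scored features
to separate cases from controls, with Platt-calibrated output in [0, 1].
Each sample s then becomes a complete weighted graph G_s = (V, E):

* nodes V = the p analytes;
* edge weight w_ij(s) = calibrated pair-classifier score on (x_i(s), x_j(s)),
  with 0.5 the uninformative value — the sample-specific adjacency matrix
  encodes which pairwise relationships look case-like *in this sample*.

Graphs may be sparsified (keep the top fraction p of edges by |w − 0.5|, or
the maximum connectivity-preserving threshold ε* found by binary search),
nodes are augmented with a structural descriptor vector
f_i = [s_i, d_i, st_i, c_i, b_i] (raw signal, normalized degree and
strength, closeness, betweenness), and the graphs are classified with a
GCN or GATv2 (NumPy implementation, reference hyperparameters: hidden 128,
2 layers, dropout 0.3, Adam lr 1e−2, plateau schedule, early stopping).
Evaluation is patient-level stratified 5-fold CV reporting ROC-AUC, F1,
sensitivity and specificity (%) on both the final-visit Primary Test Set
and the paired penultimate Early-Detection Holdout, next to five
conventional baselines (XGBoost, random forest, SVM, logistic regression,
elastic net). A synthetic-cohort generator with planted pairwise-dependence
signal, marginal markers, 4–20% assay noise and attenuated early-visit
effects makes every stage testable without access to any real cohort.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
from synolitic import (CohortSpec, ExperimentConfig, GNNConfig,
                       SparsifierSpec, generate_cohort, run_experiment)

ds = generate_cohort(CohortSpec(seed=11, n_cases=100, n_controls=100,
                                n_signal_pairs=10, n_marginal_markers=0,
                                pair_effect=0.9))
cfg = ExperimentConfig(seed=11, architectures=["GCN"],
                       sparsifiers=[SparsifierSpec("none")],
                       node_features=[True], baselines=["xgboost"],
                       gnn=GNNConfig(max_epochs=150))
report = run_experiment(ds, cfg)
print(report.summary_table())
```

prints

```
Model                 Sparsity    NodeFeat  roc_auc (%)  primary / holdout
GCN                   none        True      83.25 ± 4.39 / 65.50 ± 5.95
xgboost               -           -         81.40 ± 5.10 / 67.55 ± 12.60
```

Reading: on a 200-sample synthetic cohort whose planted signal lives in
analyte-pair dependence, the graph model recovers the final-visit signal
(mean cross-validated AUC 83.3%) and retains above-chance discrimination on
the penultimate samples, where all planted effects were halved (65.5%);
each ± is the standard deviation over the five folds.

The same pipeline is scriptable from the shell:

```bash
synolitic simulate --seed 0 --out-matrix X.csv --out-meta meta.csv
synolitic evaluate --matrix X.csv --meta meta.csv --out report/
synolitic export-pairs --matrix X.csv --meta meta.csv \
    --k 40 --hub prot_001 --out pairs.graphml
```

`evaluate` writes a tidy `report.csv` (model, sparsity, node_features,
window, fold, metric, value), a formatted `summary.txt`, and the fully
resolved configuration snapshot.

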