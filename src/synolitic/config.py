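"""Experiment configuration: one YAML/JSON file drives a full run.

The configuration mirrors the experiment grid of the benchmark study:
a list of GNN architectures crossed with sparsification strategies and the
node-feature ablation, plus the conventional-ML baselines, all evaluated
under the same patient-level k-fold protocol.  Every GNN hyperparameter is
overridable; unspecified fields keep the reference defaults.  All randomness
in a run fans out deterministically from the single ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .nn.models import GNNConfig
from .topology import SparsifierSpec

BASELINE_NAMES = ("xgboost", "random_forest", "svm",
                  "logistic_regression", "elastic_net")


@dataclass
class ExperimentConfig:
    seed: int = 0
    k_folds: int = 5
    val_fraction: float = 0.2
    svm_c: float = 1.0              # pair-classifier regularization constant
    architectures: list[str] = field(default_factory=lambda: ["GCN"])
    sparsifiers: list[SparsifierSpec] = field(default_factory=lambda: [
        SparsifierSpec("none"),
        SparsifierSpec("threshold", p=0.2),
        SparsifierSpec("threshold", p=0.8),
        SparsifierSpec("min_connected"),
    ])
    node_features: list[bool] = field(default_factory=lambda: [True, False])
    baselines: list[str] = field(default_factory=lambda: list(BASELINE_NAMES))
    gnn: GNNConfig = field(default_factory=GNNConfig)
    output_dir: str = "results"

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        for b in self.baselines:
            if b not in BASELINE_NAMES:
                raise ValueError(f"unknown baseline {b!r}")

    def replace(self, **kw) -> "ExperimentConfig":
        return replace(self, **kw)

    # -- (de)serialization ---------------------------------------------
    def resolved(self) -> dict:
        """Fully resolved config snapshot (all defaults filled) for audit."""
        d = asdict(self)
        d["sparsifiers"] = [asdict(s) for s in self.sparsifiers]
        d["gnn"] = asdict(self.gnn)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sparsifiers" in d:
            d["sparsifiers"] = [
                s if isinstance(s, SparsifierSpec) else SparsifierSpec(**s)
                for s in d["sparsifiers"]]
        if "gnn" in d and not isinstance(d["gnn"], GNNConfig):
            d["gnn"] = GNNConfig(**d["gnn"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        d = self.resolved()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
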