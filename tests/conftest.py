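import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from synolitic import (
    CohortSpec,
    SampleGraph,
    build_sample_graphs,
    compute_node_features,
    fit_pairwise_bank,
    generate_cohort,
)


def make_graph(weights, label=0, sample_id="s", raw=None, mask=None):
    """SampleGraph from a raw weight matrix (tests' shorthand)."""
    W = np.asarray(weights, dtype=float)
    V = W.shape[0]
    return SampleGraph(
        sample_id=sample_id, label=label,
        feature_names=[f"f{i}" for i in range(V)],
        weights=W,
        raw_signal=np.arange(1.0, V + 1.0) if raw is None else np.asarray(raw, float),
        edge_mask=mask,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """40-patient, 12-feature cohort with planted pair signal, both visits."""
    spec = CohortSpec(n_cases=20, n_controls=20, n_features=12,
                      n_signal_pairs=3, n_marginal_markers=2, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_graphs(small_cohort):
    """Node-feature-augmented complete graphs of the small cohort's finals."""
    from synolitic import split_by_visit
    final, _ = split_by_visit(small_cohort)
    bank = fit_pairwise_bank(final, seed=42)
    return [compute_node_features(g) for g in build_sample_graphs(bank, final)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
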