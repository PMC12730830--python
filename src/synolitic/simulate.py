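"""Synthetic proteomic cohorts with planted network-level signal.

The generator emulates the statistical structure the synolitic pipeline
assumes about serum proteomics panels:

* strictly positive, log-normally distributed concentrations whose scales
  span orders of magnitude (mixed ELISA / ECLIA / panel assays);
* multiplicative per-analyte assay noise with intra-assay coefficients of
  variation in the 4-20% band;
* a *planted pairwise-interaction signal*: designated analyte pairs whose
  joint latent distribution differs between cases and controls — cases both
  decorrelate the pair (correlation reduced by ``pair_effect``) and shift it
  antisymmetrically along the within-pair contrast (by ``pair_shift``).  The
  antisymmetric component is weak marginally but strong relative to the
  correlation-conditioned spread of the contrast, so the pair is far more
  discriminative jointly than either analyte alone — the synergy the
  pairwise edge classifiers are designed to pick up.  A pure correlation
  flip with identical margins would be invisible to linear pair classifiers;
* optional marginal "marker" analytes with a standardized mean shift in
  cases, mimicking conventional biomarkers;
* paired visits per patient: a ``final`` sample and an earlier
  ``penultimate`` sample sharing the patient's latent state, with all
  disease effects multiplied by ``attenuation`` at the earlier visit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from ._log import stage
from .cohort import VISIT_FINAL, VISIT_PENULTIMATE, OmicsDataset


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the emulated study shape: 28 cases vs 36 controls with
    100 analytes, assay CVs drawn uniformly from [0.04, 0.20], and a factor-
    0.5 attenuation of all disease effects at the penultimate (1-2 years
    earlier) visit.
    """

    n_cases: int = 28
    n_controls: int = 36
    n_features: int = 100
    n_signal_pairs: int = 8
    n_marginal_markers: int = 4
    pair_effect: float = 0.8        # correlation difference, control minus case
    pair_shift: float | None = None  # antisymmetric latent shift; default 0.45*pair_effect
    marginal_effect: float = 0.75   # standardized latent mean shift of markers
    base_rho: float = 0.7           # control-group correlation of signal pairs
    base_log_mean_range: tuple[float, float] = (0.0, 8.0)
    base_log_sd_range: tuple[float, float] = (0.3, 0.8)
    assay_cv_range: tuple[float, float] = (0.04, 0.20)
    attenuation: float = 0.5
    include_penultimate: bool = True
    within_patient_corr: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cases, self.n_controls, self.n_features) <= 0:
            raise ValueError("counts must be positive")
        max_pairs = self.n_features * (self.n_features - 1) // 2
        if self.n_signal_pairs > max_pairs:
            raise ValueError(f"n_signal_pairs exceeds C(n_features,2)={max_pairs}")
        if 2 * self.n_signal_pairs + self.n_marginal_markers > self.n_features:
            raise ValueError("not enough features for disjoint signal pairs and markers")
        if not (0.0 <= self.attenuation <= 1.0):
            raise ValueError("attenuation must be in [0, 1]")
        lo, hi = self.assay_cv_range
        if not (0.0 < lo <= hi):
            raise ValueError("invalid assay_cv_range")

    @property
    def resolved_pair_shift(self) -> float:
        return 0.45 * self.pair_effect if self.pair_shift is None else self.pair_shift

    def signal_pair_indices(self) -> list[tuple[int, int]]:
        """Disjoint planted pairs: features (0,1), (2,3), ..."""
        return [(2 * k, 2 * k + 1) for k in range(self.n_signal_pairs)]

    def marker_indices(self) -> list[int]:
        start = 2 * self.n_signal_pairs
        return list(range(start, start + self.n_marginal_markers))


def assay_noise(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal replicate noise with unit mean and CV ~ cv."""
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


def _apply_class_structure(z: np.ndarray, is_case: bool, mult: float,
                           spec: CohortSpec) -> np.ndarray:
    """Impose pair correlations/shifts and marker shifts on latent rows z."""
    z = z.copy()
    delta = spec.resolved_pair_shift
    for (i, j) in spec.signal_pair_indices():
        rho = spec.base_rho - (mult * spec.pair_effect if is_case else 0.0)
        rho = float(np.clip(rho, -0.95, 0.95))
        z[:, j] = rho * z[:, i] + np.sqrt(1.0 - rho ** 2) * z[:, j]
        if is_case:
            z[:, i] += mult * delta
            z[:, j] -= mult * delta
    if is_case:
        for k in spec.marker_indices():
            z[:, k] += mult * spec.marginal_effect
    return z


def generate_cohort(spec: CohortSpec) -> OmicsDataset:
    """Draw a cohort; identical specs (same seed) give bit-identical data."""
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    log_mean = rng.uniform(*spec.base_log_mean_range, size=p)
    log_sd = rng.uniform(*spec.base_log_sd_range, size=p)
    cvs = rng.uniform(*spec.assay_cv_range, size=p)

    sample_ids, patient_ids, visits, labels, rows = [], [], [], [], []
    visit_list = [VISIT_FINAL, VISIT_PENULTIMATE] if spec.include_penultimate \
        else [VISIT_FINAL]
    r = spec.within_patient_corr
    groups = [("case", 1, spec.n_cases), ("ctrl", 0, spec.n_controls)]
    for prefix, label, count in groups:
        for k in range(count):
            pid = f"{prefix}{k + 1:03d}"
            u = rng.normal(size=p)  # patient anchor shared across visits
            for visit in visit_list:
                e = rng.normal(size=p)
                z = (np.sqrt(r) * u + np.sqrt(1.0 - r) * e)[None, :]
                mult = 1.0 if visit == VISIT_FINAL else spec.attenuation
                z = _apply_class_structure(z, label == 1, mult, spec)
                noise = assay_noise(cvs, (1, p), rng)[0]
                x = np.exp(log_mean + log_sd * z[0]) * noise
                sample_ids.append(f"{pid}_{visit}")
                patient_ids.append(pid)
                visits.append(visit)
                labels.append(label)
                rows.append(x)

    ds = OmicsDataset(
        sample_ids=sample_ids, patient_ids=patient_ids,
        X=np.vstack(rows),
        feature_names=[f"prot_{i + 1:03d}" for i in range(p)],
        y=np.array(labels), visit=visits,
    ).validate()
    stage("generate_cohort", n_samples=ds.n_samples, n_features=p, seed=spec.seed)
    return ds


def make_null_cohort(spec: CohortSpec) -> OmicsDataset:
    """Same generator with all disease effects forced to zero.

    Labels are then independent of every feature by construction, giving the
    pipeline's no-signal calibration surface.
    """
    null_spec = replace(spec, pair_effect=0.0, pair_shift=0.0, marginal_effect=0.0)
    return generate_cohort(null_spec)


def planted_pair_auc(spec: CohortSpec, pair_index: int, n_eval: int = 2000,
                     seed: int | None = None) -> float:
    """Held-out AUC of the (quadratic) optimal pairwise rule on a signal pair.

    Draws a fresh cohort of ``n_eval`` final-visit samples, fits a quadratic
    discriminant on the log concentrations of the designated pair on one half
    and scores the other half.  Used to calibrate ``pair_effect`` so planted
    pairs are detectably, but not trivially, separable.
    """
    pairs = spec.signal_pair_indices()
    if not (0 <= pair_index < len(pairs)):
        raise ValueError(f"pair_index must be in [0, {len(pairs)})")
    i, j = pairs[pair_index]
    eval_seed = spec.seed + 7_919 if seed is None else seed
    big = replace(spec, n_cases=n_eval // 2, n_controls=n_eval - n_eval // 2,
                  include_penultimate=False, seed=eval_seed)
    ds = generate_cohort(big)
    Z = np.log(ds.X[:, [i, j]])
    y = ds.y
    rng = np.random.default_rng(eval_seed + 1)
    order = rng.permutation(len(y))
    half = len(y) // 2
    tr, te = order[:half], order[half:]
    qda = QuadraticDiscriminantAnalysis()
    qda.fit(Z[tr], y[tr])
    return float(roc_auc_score(y[te], qda.predict_proba(Z[te])[:, 1]))
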