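"""Omics cohort container and CSV/TSV input/output.

A cohort is a samples x analytes concentration matrix together with per-sample
metadata: a patient identifier, a binary case/control label, and a visit tag.
Visit tags encode the pre-diagnostic window a serum sample came from:
``final`` (< 1 year before diagnosis, or the last control sample) and
``penultimate`` (1-2 years before diagnosis).  Cohorts are always keyed by
explicit sample identifiers so downstream cross-validation folds are
reproducible across re-exports of the same files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._log import stage

VISIT_FINAL = "final"
VISIT_PENULTIMATE = "penultimate"
VALID_VISITS = (VISIT_FINAL, VISIT_PENULTIMATE)


class CohortValidationError(ValueError):
    """Raised when a cohort violates a structural invariant."""


def _as_str_list(values) -> list[str]:
    return [str(v) for v in values]


@dataclass
class OmicsDataset:
    """Validated samples x analytes cohort.

    Attributes
    ----------
    sample_ids : unique sample identifiers, one per row of ``X``.
    patient_ids : patient identifier per sample; a patient may contribute one
        ``final`` and one ``penultimate`` sample, both with the same label.
    X : non-negative concentration matrix, shape (n_samples, n_features).
    feature_names : unique analyte names, length n_features.
    y : 0/1 labels (1 = case).
    visit : visit tag per sample, ``final`` or ``penultimate``.
    """

    sample_ids: list[str]
    patient_ids: list[str]
    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray
    visit: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.sample_ids = _as_str_list(self.sample_ids)
        self.patient_ids = _as_str_list(self.patient_ids)
        self.feature_names = _as_str_list(self.feature_names)
        self.visit = _as_str_list(self.visit)

    # -- basic shape ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    # -- validation ----------------------------------------------------
    def validate(self, require_both_classes: bool = True) -> "OmicsDataset":
        n = self.n_samples
        if not (self.X.shape == (n, self.n_features)
                and len(self.y) == n
                and len(self.patient_ids) == n
                and len(self.visit) == n):
            raise CohortValidationError(
                f"inconsistent lengths: {n} sample_ids, X shape {self.X.shape}, "
                f"{len(self.y)} labels, {len(self.patient_ids)} patient_ids, "
                f"{len(self.visit)} visit tags")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise CohortValidationError(f"duplicate sample_id {dup!r}")
        dup = _first_duplicate(self.feature_names)
        if dup is not None:
            raise CohortValidationError(f"duplicate feature name {dup!r}")
        bad = np.argwhere(~np.isfinite(self.X))
        if bad.size:
            r, c = bad[0]
            raise CohortValidationError(
                f"missing or non-numeric concentration for sample "
                f"{self.sample_ids[r]!r}, feature {self.feature_names[c]!r}")
        if np.any(self.X < 0):
            r, c = np.argwhere(self.X < 0)[0]
            raise CohortValidationError(
                f"negative concentration for sample {self.sample_ids[r]!r}, "
                f"feature {self.feature_names[c]!r}")
        bad_label = [sid for sid, lab in zip(self.sample_ids, self.y) if lab not in (0, 1)]
        if bad_label:
            raise CohortValidationError(f"label not in {{0,1}} for sample {bad_label[0]!r}")
        if require_both_classes and len(set(self.y.tolist())) < 2:
            raise CohortValidationError("cohort must contain at least one sample of each class")
        bad_visit = [sid for sid, v in zip(self.sample_ids, self.visit) if v not in VALID_VISITS]
        if bad_visit:
            raise CohortValidationError(
                f"unknown visit tag for sample {bad_visit[0]!r} "
                f"(expected one of {VALID_VISITS})")
        # per-patient consistency
        per_patient: dict[str, dict] = {}
        for sid, pid, lab, vis in zip(self.sample_ids, self.patient_ids, self.y, self.visit):
            rec = per_patient.setdefault(pid, {"labels": set(), "visits": []})
            rec["labels"].add(int(lab))
            rec["visits"].append(vis)
        for pid, rec in per_patient.items():
            if len(rec["labels"]) > 1:
                raise CohortValidationError(f"patient {pid!r} has inconsistent labels")
            for v in VALID_VISITS:
                if rec["visits"].count(v) > 1:
                    raise CohortValidationError(
                        f"patient {pid!r} has more than one {v!r} sample")
        return self

    # -- subsetting ----------------------------------------------------
    def subset(self, indices: Sequence[int]) -> "OmicsDataset":
        idx = np.asarray(list(indices), dtype=int)
        return OmicsDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            X=self.X[idx].copy(),
            feature_names=list(self.feature_names),
            y=self.y[idx].copy(),
            visit=[self.visit[i] for i in idx],
        )

    def subset_by_sample_ids(self, sample_ids: Sequence[str]) -> "OmicsDataset":
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise CohortValidationError(f"unknown sample_id {missing[0]!r}")
        return self.subset([pos[s] for s in sample_ids])

    # -- persistence ---------------------------------------------------
    def write(self, matrix_path, meta_path) -> None:
        write_dataset(self, matrix_path, meta_path)

    def equals(self, other: "OmicsDataset") -> bool:
        return (self.sample_ids == other.sample_ids
                and self.patient_ids == other.patient_ids
                and self.feature_names == other.feature_names
                and self.visit == other.visit
                and np.array_equal(self.y, other.y)
                and np.array_equal(self.X, other.X))


def _first_duplicate(items: Sequence[str]):
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # round_trip parser: full-precision roundtrip of concentrations
    return pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")


def load_dataset(matrix_path, meta_path, require_both_classes: bool = True) -> OmicsDataset:
    """Load a cohort from a feature matrix file and a metadata file.

    The matrix file has a header row of feature names and one row per sample,
    keyed by its first column (sample_id).  The metadata file maps sample_id to
    patient_id, label and visit.  Binding is by sample_id, never by file order.
    """
    mat = _read_table(matrix_path)
    meta = _read_table(meta_path)
    for col in ("sample_id", "patient_id", "label", "visit"):
        if col not in meta.columns:
            raise CohortValidationError(f"metadata file missing column {col!r}")
    mat = mat.rename(columns={mat.columns[0]: "sample_id"})
    mat["sample_id"] = mat["sample_id"].astype(str)
    meta["sample_id"] = meta["sample_id"].astype(str)

    dup = _first_duplicate(list(meta["sample_id"]))
    if dup is not None:
        raise CohortValidationError(f"duplicate sample_id {dup!r} in metadata")
    dup = _first_duplicate(list(mat["sample_id"]))
    if dup is not None:
        raise CohortValidationError(f"duplicate sample_id {dup!r} in matrix")

    mat_ids = set(mat["sample_id"])
    missing = [s for s in meta["sample_id"] if s not in mat_ids]
    if missing:
        raise CohortValidationError(
            f"sample_id {missing[0]!r} in metadata but absent from matrix")
    meta_ids = set(meta["sample_id"])
    extra = [s for s in mat["sample_id"] if s not in meta_ids]
    if extra:
        raise CohortValidationError(
            f"sample_id {extra[0]!r} in matrix but absent from metadata")

    mat = mat.set_index("sample_id").loc[meta["sample_id"]]
    feature_names = list(mat.columns)
    values = mat.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first offending cell for the error message
        for c, col in enumerate(feature_names):
            coerced = pd.to_numeric(mat[col], errors="coerce")
            bad = coerced.isna() & mat[col].notna()
            if bad.any():
                sid = mat.index[bad.argmax()]
                raise CohortValidationError(
                    f"non-numeric concentration for sample {sid!r}, feature {col!r}")
        values = mat.apply(pd.to_numeric).to_numpy()

    labels = pd.to_numeric(meta["label"], errors="coerce")
    if labels.isna().any():
        sid = meta["sample_id"][labels.isna().argmax()]
        raise CohortValidationError(f"non-numeric label for sample {sid!r}")

    ds = OmicsDataset(
        sample_ids=list(meta["sample_id"]),
        patient_ids=_as_str_list(meta["patient_id"]),
        X=values.astype(float),
        feature_names=feature_names,
        y=labels.to_numpy(),
        visit=_as_str_list(meta["visit"]),
    ).validate(require_both_classes=require_both_classes)
    stage("load_dataset", n_samples=ds.n_samples, n_features=ds.n_features)
    return ds


def write_dataset(ds: OmicsDataset, matrix_path, meta_path) -> None:
    """Persist a cohort; inverse of :func:`load_dataset` to full precision."""
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    sep_m = "\t" if matrix_path.suffix.lower() in (".tsv", ".tab") else ","
    sep_t = "\t" if meta_path.suffix.lower() in (".tsv", ".tab") else ","
    mat = pd.DataFrame(ds.X, columns=ds.feature_names)
    mat.insert(0, "sample_id", ds.sample_ids)
    mat.to_csv(matrix_path, sep=sep_m, index=False, float_format="%.17g")
    meta = pd.DataFrame({
        "sample_id": ds.sample_ids,
        "patient_id": ds.patient_ids,
        "label": ds.y,
        "visit": ds.visit,
    })
    meta.to_csv(meta_path, sep=sep_t, index=False)


def split_by_visit(ds: OmicsDataset) -> tuple[OmicsDataset, OmicsDataset]:
    """Partition a cohort into (final-visit, penultimate-visit) halves.

    The two halves are disjoint, jointly exhaustive, and linked through
    ``patient_ids``.  Either half may be empty.
    """
    final_idx = [i for i, v in enumerate(ds.visit) if v == VISIT_FINAL]
    pen_idx = [i for i, v in enumerate(ds.visit) if v == VISIT_PENULTIMATE]
    return ds.subset(final_idx), ds.subset(pen_idx)
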