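"""Patient cohort data model and on-disk I/O.

A cohort couples two files:

* a clinical table (CSV, one row per patient) holding twelve screening-trial
  style variables — age, sex, race, BMI, smoking quit time, smoking
  duration, pack-years, COPD, emphysema, personal cancer history, family
  lung-cancer history, smoking status — plus the binary 2-year lung-cancer
  outcome, follow-up length, a detected-nodule flag and the train/test
  split;
* a feature store (HDF5) with one group per patient containing the
  per-scan image feature vectors (as produced upstream by a frozen CT
  encoder), their absolute acquisition days and scan ids.

Acquisition days are stored absolute; conversion to days-relative-to-first-
scan happens at encode time so truncation and time encoding stay
independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("cplp")

__all__ = [
    "MISSING",
    "SCHEMA_VARIABLES",
    "NUMERIC_VARIABLES",
    "CATEGORICAL_VARIABLES",
    "ScanFeature",
    "PatientRecord",
    "Cohort",
    "load_cohort",
    "save_cohort",
    "truncate_to_window",
    "relative_days",
    "subset_detected_nodule",
]


class _Missing:
    """Explicit sentinel for an absent clinical value (never an empty string)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

#: Canonical clinical-variable schema, in canonical (reporting) order.
SCHEMA_VARIABLES: tuple[str, ...] = (
    "age",
    "sex",
    "race",
    "bmi",
    "smoking_quit_years",
    "smoking_duration_years",
    "pack_years",
    "copd",
    "emphysema",
    "personal_cancer_history",
    "family_lung_cancer_history",
    "smoking_status",
)

NUMERIC_VARIABLES: tuple[str, ...] = (
    "age", "bmi", "smoking_quit_years", "smoking_duration_years", "pack_years",
)
CATEGORICAL_VARIABLES: tuple[str, ...] = tuple(
    v for v in SCHEMA_VARIABLES if v not in NUMERIC_VARIABLES
)
_FLAG_VARIABLES = ("copd", "emphysema", "personal_cancer_history",
                   "family_lung_cancer_history")

_META_COLUMNS = ("patient_id", "label", "followup_days", "nodule_detected", "split")


@dataclass(frozen=True)
class ScanFeature:
    """One chest-CT scan: an opaque id, an absolute acquisition day and a
    fixed-dimension feature vector."""

    scan_id: str
    acquisition_day: int
    features: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "features",
                           np.asarray(self.features, dtype=np.float32))
        if not np.isfinite(self.acquisition_day):
            raise ValueError(f"non-finite acquisition_day for scan {self.scan_id}")


@dataclass
class PatientRecord:
    """One patient: ordered scan sequence, clinical variables, outcome."""

    patient_id: str
    scans: list[ScanFeature]
    variables: dict[str, Any]
    label: int
    followup_days: int
    nodule_detected: int
    split: str

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")
        if self.followup_days < 0:
            raise ValueError("followup_days must be non-negative")
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be train|test, got {self.split!r}")
        unknown = set(self.variables) - set(SCHEMA_VARIABLES)
        if unknown:
            raise ValueError(f"unknown clinical variables: {sorted(unknown)}")
        if not self.scans:
            raise ValueError(f"patient {self.patient_id} has no scans")
        self.scans = sorted(self.scans, key=lambda s: s.acquisition_day)


@dataclass
class Cohort:
    """A validated list of patients sharing one feature dimension."""

    patients: list[PatientRecord]
    feature_dim: int

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_ids in cohort")
        for p in self.patients:
            for s in p.scans:
                if s.features.shape != (self.feature_dim,):
                    raise ValueError(
                        f"feature dimension mismatch for patient {p.patient_id} "
                        f"scan {s.scan_id}: expected {self.feature_dim}, "
                        f"got {s.features.shape}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterable[PatientRecord]:
        return iter(self.patients)

    def split_subset(self, split: str) -> "Cohort":
        return Cohort([p for p in self.patients if p.split == split],
                      self.feature_dim)


def _parse_variable(name: str, raw) -> Any:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return MISSING
    if name in NUMERIC_VARIABLES:
        return float(raw)
    val = str(raw).strip().lower()
    if name in _FLAG_VARIABLES:
        if val in ("1", "1.0", "true", "yes"):
            return "yes"
        if val in ("0", "0.0", "false", "no"):
            return "no"
        raise ValueError(f"cannot parse flag variable {name}={raw!r}")
    return val


def load_cohort(clinical_table_path: str | Path,
                feature_store_path: str | Path) -> Cohort:
    """Read the clinical CSV and HDF5 feature store into a validated Cohort.

    Raises a `KeyError` naming the patient if a table row has no scans in
    the store, and `ValueError` on feature-dimension mismatch. Unknown CSV
    columns are ignored with a logged warning.
    """
    table = pd.read_csv(clinical_table_path, dtype={"patient_id": str})
    required = set(_META_COLUMNS)
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"clinical table missing columns: {sorted(missing_cols)}")
    known = set(SCHEMA_VARIABLES) | required
    unknown = [c for c in table.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown clinical-table columns: %s", unknown)

    patients: list[PatientRecord] = []
    feature_dim: int | None = None
    with h5py.File(feature_store_path, "r") as store:
        grp = store["patients"]
        for row in table.itertuples(index=False):
            pid = str(row.patient_id)
            if pid not in grp:
                raise KeyError(f"patient {pid!r} has no scans in the feature store")
            g = grp[pid]
            feats = np.asarray(g["features"], dtype=np.float32)
            days = np.asarray(g["days"], dtype=np.int64)
            scan_ids = [s.decode() if isinstance(s, bytes) else str(s)
                        for s in np.asarray(g["scan_ids"])]
            if feats.ndim != 2 or len(days) != len(feats):
                raise ValueError(f"malformed feature group for patient {pid!r}")
            if feature_dim is None:
                feature_dim = feats.shape[1]
            elif feats.shape[1] != feature_dim:
                raise ValueError(
                    f"feature dimension mismatch: patient {pid!r} has "
                    f"{feats.shape[1]}-d features, cohort has {feature_dim}-d")
            scans = [ScanFeature(scan_ids[t], int(days[t]), feats[t])
                     for t in range(len(days))]
            variables = {v: _parse_variable(v, getattr(row, v))
                         for v in SCHEMA_VARIABLES if v in table.columns}
            patients.append(PatientRecord(
                patient_id=pid,
                scans=scans,
                variables=variables,
                label=int(row.label),
                followup_days=int(row.followup_days),
                nodule_detected=int(row.nodule_detected),
                split=str(row.split),
            ))
    if feature_dim is None:
        raise ValueError("clinical table has no rows")
    return Cohort(patients, feature_dim)


def save_cohort(cohort: Cohort, clinical_table_path: str | Path,
                feature_store_path: str | Path) -> None:
    """Write the cohort back to the CSV + HDF5 pair `load_cohort` reads."""
    rows = []
    for p in cohort.patients:
        row: dict[str, Any] = {"patient_id": p.patient_id}
        for v in SCHEMA_VARIABLES:
            val = p.variables.get(v, MISSING)
            row[v] = "" if val is MISSING else val
        row.update(label=p.label, followup_days=p.followup_days,
                   nodule_detected=p.nodule_detected, split=p.split)
        rows.append(row)
    cols = ["patient_id", *SCHEMA_VARIABLES, "label", "followup_days",
            "nodule_detected", "split"]
    pd.DataFrame(rows, columns=cols).to_csv(clinical_table_path, index=False)

    with h5py.File(feature_store_path, "w") as store:
        grp = store.create_group("patients")
        for p in cohort.patients:
            g = grp.create_group(p.patient_id)
            g.create_dataset("features", data=np.stack(
                [s.features for s in p.scans]).astype(np.float32))
            g.create_dataset("days", data=np.asarray(
                [s.acquisition_day for s in p.scans], dtype=np.int32))
            g.create_dataset("scan_ids", data=np.asarray(
                [s.scan_id for s in p.scans], dtype=h5py.string_dtype()))


def truncate_to_window(patient: PatientRecord, max_len: int = 3) -> PatientRecord:
    """Keep the `max_len` chronologically latest scans (order preserved).

    The encoder consumes at most three screens; patients with more keep the
    latest window, matching latest-token pooling.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(patient.scans) <= max_len:
        return patient
    return replace(patient, scans=patient.scans[-max_len:])


def relative_days(patient: PatientRecord) -> np.ndarray:
    """Days of each retained scan relative to the earliest retained scan."""
    days = np.asarray([s.acquisition_day for s in patient.scans], dtype=np.int64)
    return days - days[0]


def subset_detected_nodule(cohort: Cohort) -> Cohort:
    """Test-split patients with a detected lung nodule.

    This is the cohort on which benign-vs-malignant discrimination is
    evaluated; training patients are always excluded.
    """
    keep = [p for p in cohort.patients
            if p.split == "test" and p.nodule_detected == 1]
    return Cohort(keep, cohort.feature_dim)
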