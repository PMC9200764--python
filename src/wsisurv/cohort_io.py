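"""Cohort tables and patient-level split plans.

A cohort is a set of patients with right-censored overall-survival
follow-up and one or more slide references each.  All splitting is done
at the patient level: a patient's slides never straddle train and test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "PatientRecord",
    "Cohort",
    "Fold",
    "SplitPlan",
    "load_cohort",
    "write_cohort",
    "make_split_plan",
]

#: Mean Gregorian month length, used to convert follow-up days to months.
DAYS_PER_MONTH = 30.44


class SchemaError(ValueError):
    """A required column is missing from a cohort table."""


class CohortValidationError(ValueError):
    """A row of a cohort table violates a field invariant."""


@dataclass
class PatientRecord:
    """One patient: survival follow-up plus slide references.

    Parameters
    ----------
    patient_id : str
        Unique identifier within a cohort.
    slide_ids : list of str
        One or more slide references (paths or ids) for this patient.
    time_months : float
        Follow-up time in months, nonnegative.
    event : int
        1 if the event (death) was observed, 0 if censored.
    covariates : dict
        Optional clinical covariates (age, gender, stage, ...).
    """

    patient_id: str
    slide_ids: list[str]
    time_months: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.slide_ids) < 1:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: needs at least one slide"
            )
        if not np.isfinite(self.time_months) or self.time_months < 0:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: time_months must be >= 0, "
                f"got {self.time_months!r}"
            )
        if self.event not in (0, 1):
            raise CohortValidationError(
                f"patient {self.patient_id!r}: event must be 0 or 1, "
                f"got {self.event!r}"
            )


@dataclass
class Cohort:
    """A named, nonempty collection of patients with unique ids."""

    patients: list[PatientRecord]
    name: str = "cohort"

    def __post_init__(self) -> None:
        if not self.patients:
            raise CohortValidationError("cohort is empty")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __getitem__(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def times(self) -> np.ndarray:
        return np.array([p.time_months for p in self.patients], dtype=float)

    def events(self) -> np.ndarray:
        return np.array([p.event for p in self.patients], dtype=int)


@dataclass
class Fold:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]


@dataclass
class SplitPlan:
    """k disjoint test folds; within each fold, a train/val split of the rest."""

    folds: list[Fold]
    k: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "folds": [
                {"train": f.train_ids, "val": f.val_ids, "test": f.test_ids}
                for f in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        folds = [
            Fold(f["train"], f["val"], f["test"]) for f in payload["folds"]
        ]
        return cls(folds=folds, k=payload["k"], seed=payload["seed"])


def _resolve_columns(columns, schema):
    """Map logical roles onto concrete column names."""
    schema = dict(schema or {})
    resolved = {}
    for role, default_names in (
        ("patient_id", ["patient_id"]),
        ("slide_path", ["slide_path", "slide_id"]),
        ("event", ["event"]),
    ):
        name = schema.get(role)
        if name is None:
            name = next((c for c in default_names if c in columns), None)
        if name is None or name not in columns:
            raise SchemaError(f"missing required column for {role!r}")
        resolved[role] = name

    time_col = schema.get("time")
    unit = schema.get("time_unit")
    if time_col is None:
        if "time_months" in columns:
            time_col, unit = "time_months", "months"
        elif "time_days" in columns:
            time_col, unit = "time_days", "days"
        else:
            raise SchemaError("missing required column for 'time'")
    if time_col not in columns:
        raise SchemaError(f"missing required column for 'time' ({time_col!r})")
    if unit is None:
        unit = "days" if "day" in time_col.lower() else "months"
    if unit not in ("days", "months"):
        raise SchemaError(f"time_unit must be 'days' or 'months', got {unit!r}")
    resolved["time"] = time_col
    resolved["time_unit"] = unit
    return resolved


def load_cohort(path, schema=None, name=None) -> Cohort:
    """Read a delimited cohort table into a :class:`Cohort`.

    One row per slide; rows sharing a patient id are merged into a single
    :class:`PatientRecord` with several ``slide_ids``.  Times given in days
    are converted to months by dividing by ``DAYS_PER_MONTH``.  Any column
    beyond the required four is kept as a covariate and must be constant
    within a patient.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    cols = _resolve_columns(df.columns, schema)
    required = {cols["patient_id"], cols["slide_path"], cols["time"], cols["event"]}
    covariate_cols = [c for c in df.columns if c not in required]

    patients = []
    for pid, group in df.groupby(cols["patient_id"], sort=False):
        first = group.iloc[0]
        row_no = int(first.name) + 2  # 1-based with header line
        time = float(first[cols["time"]])
        event_raw = first[cols["event"]]
        if not float(event_raw) in (0.0, 1.0):
            raise CohortValidationError(
                f"row {row_no} (patient {pid!r}): event must be 0 or 1, "
                f"got {event_raw!r}"
            )
        if time < 0 or not np.isfinite(time):
            raise CohortValidationError(
                f"row {row_no} (patient {pid!r}): negative or non-finite time"
            )
        if group[cols["time"]].nunique() > 1 or group[cols["event"]].nunique() > 1:
            raise CohortValidationError(
                f"patient {pid!r}: inconsistent time/event across slide rows"
            )
        if cols["time_unit"] == "days":
            time = time / DAYS_PER_MONTH
        covariates = {}
        for c in covariate_cols:
            v = first[c]
            covariates[c] = None if pd.isna(v) else v
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                slide_ids=[str(s) for s in group[cols["slide_path"]]],
                time_months=time,
                event=int(event_raw),
                covariates=covariates,
            )
        )
    return Cohort(patients=patients, name=name or path.stem)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV, one row per slide, times in months."""
    rows = []
    for p in cohort.patients:
        for sid in p.slide_ids:
            row = {
                "patient_id": p.patient_id,
                "slide_path": sid,
                "time_months": repr(float(p.time_months)),
                "event": p.event,
            }
            row.update(p.covariates)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def make_split_plan(cohort: Cohort, k: int, fractions=(0.7, 0.1), seed: int = 0) -> SplitPlan:
    """Patient-level k-fold plan with a train/val split inside each fold.

    The k test sets partition the cohort (sizes differ by at most one).
    Within each fold the remaining patients are divided train/val in the
    ratio ``fractions`` prescribes for the whole cohort, e.g. the default
    (0.7, 0.1) with k=5 yields 70/10/20 overall.  Deterministic given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(cohort)
    if k > n:
        raise ValueError(f"k={k} exceeds number of patients ({n})")
    train_f, val_f = float(fractions[0]), float(fractions[1])
    if train_f <= 0 or val_f <= 0 or train_f + val_f >= 1:
        raise ValueError("fractions must be positive with train+val < 1")

    rng = np.random.default_rng(seed)
    ids = np.array(cohort.patient_ids)
    perm = ids[rng.permutation(n)]
    test_sets = np.array_split(perm, k)

    folds = []
    val_share = val_f / (train_f + val_f)
    for test in test_sets:
        rest = np.array([i for i in perm if i not in set(test)])
        rest = rest[rng.permutation(len(rest))]
        n_val = int(round(len(rest) * val_share))
        n_val = min(max(n_val, 1), len(rest) - 1)
        folds.append(
            Fold(
                train_ids=sorted(rest[n_val:].tolist()),
                val_ids=sorted(rest[:n_val].tolist()),
                test_ids=sorted(test.tolist()),
            )
        )
    return SplitPlan(folds=folds, k=k, seed=seed)
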