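"""Data model, I/O and cohort-construction filters for longitudinal trial data.

A :class:`Cohort` holds one record per trial participant: a treatment-arm
label plus a ``n_visits x n_vars`` matrix of measurements on a named visit
schedule.  The default schema matches a two-arm blood-pressure trial with
twelve visits (randomization through month 27) and three variables per
visit: systolic blood pressure (mmHg), diastolic blood pressure (mmHg) and
the count of prescribed antihypertensive medications.

An :class:`EventTable` holds long-format EHR vitals (patient, variable,
timestamp, value) together with an ICD-9 diagnosis list, and is turned into
a fixed-width design matrix by :func:`first_k_measurements`.

Normalization maps each variable to ``[-1, 1]`` using *fixed, a-priori
physiologic ranges* rather than data-derived minima/maxima, so that no
privacy budget is spent on range estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "DEFAULT_SCHEDULE",
    "DEFAULT_VARIABLES",
    "DEFAULT_RANGES",
    "COUNT_VARIABLES",
    "CohortSchema",
    "ParticipantRecord",
    "Cohort",
    "EventTable",
    "SchemaError",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "filter_complete",
    "split_train_test",
    "label_heart_failure",
    "first_k_measurements",
    "normalize",
    "denormalize",
]

ARMS = ("standard", "intensive")

#: Visit labels: randomization visit then months 1-27.
DEFAULT_SCHEDULE = ("RZ", "1M", "2M", "3M", "6M", "9M", "12M", "15M", "18M", "21M", "24M", "27M")

DEFAULT_VARIABLES = ("SBP", "DBP", "MED")

#: Fixed physiologic normalization ranges (data-independent by design).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "SBP": (60.0, 250.0),
    "DBP": (30.0, 150.0),
    "MED": (0.0, 10.0),
}

#: Variables denormalized to non-negative integer counts.
COUNT_VARIABLES = ("MED",)


class SchemaError(ValueError):
    """A required column is absent or the schema is inconsistent."""


class CohortParseError(ValueError):
    """A cell could not be parsed as a number."""


@dataclass(frozen=True)
class CohortSchema:
    """Naming map between a cohort CSV and the in-memory layout.

    Columns are named ``<visit>_<variable>`` (e.g. ``RZ_SBP``), plus an
    ``id`` and an ``arm`` column.
    """

    schedule: tuple[str, ...] = DEFAULT_SCHEDULE
    variables: tuple[str, ...] = DEFAULT_VARIABLES
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    count_variables: tuple[str, ...] = COUNT_VARIABLES
    id_column: str = "id"
    arm_column: str = "arm"

    @property
    def n_visits(self) -> int:
        return len(self.schedule)

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def value_columns(self) -> list[str]:
        """Column names in record layout: visit-major, variable within visit."""
        return [f"{v}_{x}" for v in self.schedule for x in self.variables]


DEFAULT_SCHEMA = CohortSchema()


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: arm label plus a ``n_visits x n_vars`` value matrix."""

    id: str
    arm: str
    values: np.ndarray  # shape (n_visits, n_vars)
    visit_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != len(self.visit_labels):
            raise ValueError(
                f"values shape {values.shape} does not match {len(self.visit_labels)} visits"
            )
        object.__setattr__(self, "values", values)

    @property
    def n_visits(self) -> int:
        return self.values.shape[0]

    def is_complete(self, n_visits: int | None = None) -> bool:
        rows = self.values if n_visits is None else self.values[:n_visits]
        return bool(np.isfinite(rows).all())


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of participant records sharing a schema."""

    records: tuple[ParticipantRecord, ...]
    schema: CohortSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("participant ids must be unique")
        for r in self.records:
            if r.visit_labels != self.schema.schedule:
                raise ValueError(f"record {r.id} schedule does not match cohort schema")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def arms(self) -> np.ndarray:
        """Arm indicator per record: 0 = standard, 1 = intensive."""
        return np.array([ARMS.index(r.arm) for r in self.records], dtype=int)

    def values(self) -> np.ndarray:
        """Stacked value array, shape ``(n, n_visits, n_vars)``."""
        if not self.records:
            return np.empty((0, self.schema.n_visits, self.schema.n_vars))
        return np.stack([r.values for r in self.records])

    def feature_matrix(self) -> np.ndarray:
        """Flat feature matrix, shape ``(n, n_vars * n_visits)``.

        Variable-major ordering: all visits of the first variable, then all
        visits of the second, and so on.  This is the canonical layout used
        by the GAN, the classifiers and the pairwise-correlation heatmaps.
        """
        vals = self.values()  # (n, visits, vars)
        return vals.transpose(0, 2, 1).reshape(len(self), -1)

    def feature_names(self) -> list[str]:
        return [f"{x}_{v}" for x in self.schema.variables for v in self.schema.schedule]

    def subset(self, indices: Iterable[int]) -> "Cohort":
        return Cohort(tuple(self.records[i] for i in indices), self.schema)


@dataclass(frozen=True)
class EventTable:
    """Long-format vitals plus an ICD-9 diagnosis list.

    ``measurements`` columns: patient_id, variable, time, value.
    ``diagnoses`` columns: patient_id, code.
    """

    measurements: pd.DataFrame
    diagnoses: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"patient_id", "variable", "time", "value"}
        if not need.issubset(self.measurements.columns):
            raise SchemaError(f"measurements table needs columns {sorted(need)}")
        need_dx = {"patient_id", "code"}
        if not need_dx.issubset(self.diagnoses.columns):
            raise SchemaError(f"diagnoses table needs columns {sorted(need_dx)}")

    @property
    def patient_ids(self) -> list:
        return list(pd.unique(self.measurements["patient_id"]))


# ---------------------------------------------------------------------------
# I/O


def _parse_arm(raw: object, row: int) -> str:
    text = str(raw).strip().lower()
    if text not in ARMS:
        raise CohortParseError(f"row {row}: unrecognized arm label {raw!r}")
    return text


def read_cohort(path, schema: CohortSchema = DEFAULT_SCHEMA) -> Cohort:
    """Read a wide-format cohort CSV (one row per participant).

    Empty cells and ``NA`` are treated as missing-value sentinels and kept
    as NaN; use :func:`filter_complete` to drop incomplete records.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in [schema.id_column, schema.arm_column, *schema.value_columns()]
               if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    records = []
    for row_idx, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        arm = _parse_arm(row[schema.arm_column], row_idx)
        values = np.empty((schema.n_visits, schema.n_vars))
        for i, visit in enumerate(schema.schedule):
            for j, var in enumerate(schema.variables):
                col = f"{visit}_{var}"
                cell = row[col].strip()
                if cell == "" or cell.upper() == "NA":
                    values[i, j] = np.nan
                    continue
                try:
                    values[i, j] = float(cell)
                except ValueError as exc:
                    raise CohortParseError(
                        f"row {row_idx}, column {col}: cannot parse {cell!r} as a number"
                    ) from exc
        records.append(
            ParticipantRecord(str(row[schema.id_column]), arm, values, schema.schedule)
        )
    return Cohort(tuple(records), schema)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort in the same wide CSV dialect that :func:`read_cohort` reads."""
    schema = cohort.schema
    data: dict[str, list] = {schema.id_column: cohort.ids,
                             schema.arm_column: [r.arm for r in cohort]}
    vals = cohort.values()
    for i, visit in enumerate(schema.schedule):
        for j, var in enumerate(schema.variables):
            col_vals = vals[:, i, j] if len(cohort) else np.array([])
            if var in schema.count_variables:
                data[f"{visit}_{var}"] = [
                    "" if not np.isfinite(v) else str(int(round(v))) for v in col_vals
                ]
            else:
                data[f"{visit}_{var}"] = [
                    "" if not np.isfinite(v) else repr(float(v)) for v in col_vals
                ]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort construction


def filter_complete(cohort: Cohort, required_visits: int | None = None) -> Cohort:
    """Keep only records with every value present at the first ``required_visits`` visits.

    Mirrors the trial-inclusion rule of keeping participants with blood
    pressure measurements at each of the first twelve visits.  Order is
    preserved; the operation is idempotent.
    """
    if required_visits is None:
        required_visits = cohort.schema.n_visits
    if required_visits > cohort.schema.n_visits:
        raise ValueError(
            f"required_visits={required_visits} exceeds schedule length {cohort.schema.n_visits}"
        )
    kept = tuple(r for r in cohort.records if r.is_complete(required_visits))
    return Cohort(kept, cohort.schema)


def split_train_test(cohort: Cohort, n_train: int, seed: int) -> tuple[Cohort, Cohort]:
    """Seeded uniform shuffle into disjoint (train, test) cohorts."""
    if n_train >= len(cohort):
        raise ValueError(f"n_train={n_train} must be < cohort size {len(cohort)}")
    if n_train < 0:
        raise ValueError("n_train must be non-negative")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    train_idx = sorted(order[:n_train].tolist())
    test_idx = sorted(order[n_train:].tolist())
    return cohort.subset(train_idx), cohort.subset(test_idx)


def label_heart_failure(events: EventTable, codes: Sequence[str]) -> pd.Series:
    """Binary heart-failure label per patient: 1 iff any diagnosis is in ``codes``.

    Matching is exact on whitespace-stripped code text; prefix semantics
    ("428" matching "428.x") are deliberately not applied — supply the full
    enumerated list if children should count.
    """
    code_set = {str(c).strip() for c in codes}
    patients = events.patient_ids
    if len(events.diagnoses):
        dx = events.diagnoses.assign(code=events.diagnoses["code"].astype(str).str.strip())
        flagged = set(dx.loc[dx["code"].isin(code_set), "patient_id"])
    else:
        flagged = set()
    return pd.Series([1 if p in flagged else 0 for p in patients], index=patients, name="label")


def first_k_measurements(
    events: EventTable, variables: Sequence[str], k: int
) -> pd.DataFrame:
    """Per patient, the earliest ``k`` values of each variable, concatenated.

    Complete-case rule: a patient lacking ``k`` measurements for *any*
    listed variable is dropped.  Output columns are ``<var>_t<1..k>`` in the
    given variable order; the row index is the patient id (input order of
    first appearance preserved).
    """
    meas = events.measurements
    known = set(meas["variable"].unique())
    unknown = [v for v in variables if v not in known]
    if unknown:
        raise ValueError(f"unknown variable name(s): {', '.join(map(str, unknown))}")
    if k <= 0:
        raise ValueError("k must be positive")

    columns = [f"{v}_t{t + 1}" for v in variables for t in range(k)]
    rows, index = [], []
    grouped = meas.sort_values("time", kind="stable").groupby("patient_id", sort=False)
    by_patient = {pid: g for pid, g in grouped}
    for pid in events.patient_ids:
        g = by_patient.get(pid)
        if g is None:
            continue
        row = []
        for var in variables:
            vals = g.loc[g["variable"] == var, "value"].to_numpy(dtype=float)
            if len(vals) < k:
                row = None
                break
            row.extend(vals[:k])
        if row is not None:
            rows.append(row)
            index.append(pid)
    return pd.DataFrame(rows, index=pd.Index(index, name="patient_id"), columns=columns)


# ---------------------------------------------------------------------------
# Normalization


def _range_arrays(schema: CohortSchema) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([schema.ranges[v][0] for v in schema.variables])
    hi = np.array([schema.ranges[v][1] for v in schema.variables])
    return lo, hi


def normalize(cohort: Cohort) -> np.ndarray:
    """Map the cohort's feature matrix onto ``[-1, 1]`` per variable.

    Uses the schema's fixed ranges; values outside a range are clamped with
    a warning rather than rejected.  Returns shape ``(n, n_vars * n_visits)``
    in the variable-major layout of :meth:`Cohort.feature_matrix`.
    """
    schema = cohort.schema
    lo, hi = _range_arrays(schema)
    vals = cohort.values()  # (n, visits, vars)
    below, above = vals < lo, vals > hi
    if below.any() or above.any():
        warnings.warn(
            f"{int(below.sum() + above.sum())} value(s) outside fixed ranges were clamped",
            stacklevel=2,
        )
        vals = np.clip(vals, lo, hi)
    scaled = 2.0 * (vals - lo) / (hi - lo) - 1.0
    return scaled.transpose(0, 2, 1).reshape(len(cohort), -1)


def denormalize(
    matrix: np.ndarray,
    arms: np.ndarray,
    schema: CohortSchema = DEFAULT_SCHEMA,
    id_prefix: str = "syn",
) -> Cohort:
    """Inverse of :func:`normalize`: build a cohort from normalized features.

    Values are clamped to each variable's range; count variables are rounded
    to non-negative integers.  ``arms`` holds 0/1 arm indicators per row.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    expected = schema.n_vars * schema.n_visits
    if matrix.ndim != 2 or matrix.shape[1] != expected:
        raise ValueError(f"matrix must have shape (n, {expected}), got {matrix.shape}")
    lo, hi = _range_arrays(schema)
    vals = matrix.reshape(n, schema.n_vars, schema.n_visits).transpose(0, 2, 1)
    vals = (np.clip(vals, -1.0, 1.0) + 1.0) / 2.0 * (hi - lo) + lo
    for j, var in enumerate(schema.variables):
        if var in schema.count_variables:
            vals[:, :, j] = np.clip(np.round(vals[:, :, j]), 0, None)
    width = max(5, len(str(n)))
    records = tuple(
        ParticipantRecord(f"{id_prefix}-{i:0{width}d}", ARMS[int(arms[i])], vals[i], schema.schedule)
        for i in range(n)
    )
    return Cohort(records, schema)


def cohort_from_arrays(
    values: np.ndarray,
    arms: Sequence[int] | np.ndarray,
    schema: CohortSchema = DEFAULT_SCHEMA,
    ids: Sequence[str] | None = None,
) -> Cohort:
    """Build a cohort from a ``(n, n_visits, n_vars)`` value array and arm indicators."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if ids is None:
        width = max(5, len(str(n)))
        ids = [f"p-{i:0{width}d}" for i in range(n)]
    records = tuple(
        ParticipantRecord(str(ids[i]), ARMS[int(arms[i])], values[i], schema.schedule)
        for i in range(n)
    )
    return Cohort(records, schema)
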