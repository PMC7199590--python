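"""Domain types and CSV I/O for the patient-level cohort and longitudinal RDW tables.

A cohort row holds one adult ARDS patient: demographics, severity markers
(SOFA, PaO2/FiO2), the red-cell distribution width (RDW) closest to the time
of ARDS diagnosis, and three nested mortality flags (ICU, in-hospital,
90-day). Longitudinal RDW measurements live in a separate long-format table,
one row per (patient, day) measurement.

Outcome nesting is enforced: death in the ICU entails in-hospital death,
which entails death by day 90. Validation is total — any invalid value is a
structured error naming the row and field, never a silent coercion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

SEXES = ("male", "female")
COMORBIDITY_CATEGORIES = ("0", "1", "2", "3plus")

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "comorbidity_category",
    "sofa",
    "pf_ratio",
    "rdw_baseline",
    "icu_death",
    "hosp_death",
    "death_90d",
)

RDW_LONG_COLUMNS = ("patient_id", "time_days", "rdw")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates and nested mortality outcomes.

    Attributes
    ----------
    patient_id : unique identifier.
    age : years, >= 18.
    sex : "male" or "female".
    comorbidity_category : count of comorbid conditions collapsed to
        {"0", "1", "2", "3plus"}.
    sofa : Sequential Organ Failure Assessment score, integer 0-24.
    pf_ratio : first documented PaO2/FiO2 after diagnosis, mmHg, > 0.
    rdw_baseline : RDW (%) closest to the time of ARDS diagnosis, > 0.
    icu_death, hosp_death, death_90d : mortality flags; icu_death implies
        hosp_death implies death_90d.
    """

    patient_id: str
    age: float
    sex: str
    comorbidity_category: str
    sofa: int
    pf_ratio: float
    rdw_baseline: float
    icu_death: bool
    hosp_death: bool
    death_90d: bool

    def __post_init__(self) -> None:
        pid = self.patient_id

        def bad(fieldname: str, msg: str) -> ValidationError:
            return ValidationError(
                f"patient {pid!r}: {fieldname} {msg}", row=pid, field=fieldname
            )

        if not self.patient_id:
            raise ValidationError("empty patient_id", field="patient_id")
        if not np.isfinite(self.age) or self.age < 18:
            raise bad("age", f"must be a finite value >= 18, got {self.age}")
        if self.sex not in SEXES:
            raise bad("sex", f"must be one of {SEXES}, got {self.sex!r}")
        if self.comorbidity_category not in COMORBIDITY_CATEGORIES:
            raise bad(
                "comorbidity_category",
                f"must be one of {COMORBIDITY_CATEGORIES}, got {self.comorbidity_category!r}",
            )
        if int(self.sofa) != self.sofa or not 0 <= self.sofa <= 24:
            raise bad("sofa", f"must be an integer in [0, 24], got {self.sofa}")
        if not np.isfinite(self.pf_ratio) or self.pf_ratio <= 0:
            raise bad("pf_ratio", f"must be > 0, got {self.pf_ratio}")
        if not np.isfinite(self.rdw_baseline) or self.rdw_baseline <= 0:
            raise bad("rdw_baseline", f"must be > 0, got {self.rdw_baseline}")
        if self.icu_death and not self.hosp_death:
            raise bad("hosp_death", "ICU death implies in-hospital death")
        if self.hosp_death and not self.death_90d:
            raise bad("death_90d", "in-hospital death implies 90-day death")


@dataclass(frozen=True)
class CohortTable:
    """Ordered collection of validated :class:`PatientRecord` with unique ids."""

    records: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"duplicate patient_id values: {dupes}", field="patient_id"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Return the cohort as a pandas DataFrame (one row per patient)."""
        return pd.DataFrame(
            [[getattr(r, c) for c in COHORT_COLUMNS] for r in self.records],
            columns=list(COHORT_COLUMNS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortTable":
        """Build a validated cohort from a DataFrame with the cohort columns."""
        missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(
                f"cohort table missing required column(s): {missing}",
                column=missing[0],
            )
        records = []
        for idx, row in frame.iterrows():
            try:
                records.append(
                    PatientRecord(
                        patient_id=str(row["patient_id"]),
                        age=float(row["age"]),
                        sex=str(row["sex"]),
                        comorbidity_category=str(row["comorbidity_category"]),
                        sofa=int(row["sofa"]),
                        pf_ratio=float(row["pf_ratio"]),
                        rdw_baseline=float(row["rdw_baseline"]),
                        icu_death=_parse_flag(row["icu_death"], idx, "icu_death"),
                        hosp_death=_parse_flag(row["hosp_death"], idx, "hosp_death"),
                        death_90d=_parse_flag(row["death_90d"], idx, "death_90d"),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"row {idx}: {exc}", row=idx) from exc
            except ValidationError as exc:
                raise ValidationError(f"row {idx}: {exc}", row=idx, field=exc.field) from exc
        return cls(records=tuple(records))


@dataclass(frozen=True)
class RDWSeries:
    """One patient's longitudinal RDW measurements.

    Times are days since ARDS diagnosis (>= 0, strictly increasing);
    values are RDW percentages (> 0).
    """

    patient_id: str
    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        pid = self.patient_id
        if len(self.times) != len(self.values):
            raise ValidationError(
                f"patient {pid!r}: times and values differ in length", row=pid
            )
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size and (not np.all(np.isfinite(t)) or t.min() < 0):
            raise ValidationError(
                f"patient {pid!r}: time_days must be finite and >= 0",
                row=pid,
                field="time_days",
            )
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"patient {pid!r}: times must be strictly increasing "
                "(duplicate or out-of-order measurement times)",
                row=pid,
                field="time_days",
            )
        if v.size and (not np.all(np.isfinite(v)) or v.min() <= 0):
            raise ValidationError(
                f"patient {pid!r}: rdw must be finite and > 0", row=pid, field="rdw"
            )

    @property
    def n_obs(self) -> int:
        return len(self.times)

    @property
    def observations(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.times, self.values))


def _parse_flag(value: object, row: object, fieldname: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value in (0, 1):
        return bool(value)
    if isinstance(value, str) and value.strip() in ("0", "1"):
        return value.strip() == "1"
    raise ValidationError(
        f"{fieldname} must be 0/1, got {value!r}", row=row, field=fieldname
    )


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a patient-level cohort CSV.

    The file must be comma-separated UTF-8 with a header row naming the
    columns in :data:`COHORT_COLUMNS`; boolean flags are coded 0/1.
    """
    frame = pd.read_csv(path)
    return CohortTable.from_frame(frame)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV (booleans as 0/1, round-trips with read_cohort)."""
    frame = cohort.to_frame()
    for c in ("icu_death", "hosp_death", "death_90d"):
        frame[c] = frame[c].astype(int)
    frame.to_csv(path, index=False)


def read_rdw_long(path: str | Path) -> tuple[RDWSeries, ...]:
    """Read a long-format RDW measurement CSV into one series per patient.

    Rows may arrive in any time order; each returned series is sorted by
    time. A duplicated (patient, time) pair or a negative time is rejected.
    """
    frame = pd.read_csv(path)
    missing = [c for c in RDW_LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"rdw long table missing required column(s): {missing}", column=missing[0]
        )
    series = []
    for pid, group in frame.groupby("patient_id", sort=False):
        g = group.sort_values("time_days")
        times = g["time_days"].astype(float).to_numpy()
        if np.any(np.diff(times) == 0):
            raise ValidationError(
                f"patient {pid!r}: duplicate time_days values",
                row=pid,
                field="time_days",
            )
        series.append(
            RDWSeries(
                patient_id=str(pid),
                times=tuple(times),
                values=tuple(g["rdw"].astype(float)),
            )
        )
    return tuple(series)


def write_rdw_long(series: Iterable[RDWSeries], path: str | Path) -> None:
    """Write RDW series to long-format CSV (round-trips with read_rdw_long)."""
    rows = [
        (s.patient_id, t, v)
        for s in series
        for t, v in zip(s.times, s.values)
    ]
    pd.DataFrame(rows, columns=list(RDW_LONG_COLUMNS)).to_csv(path, index=False)
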