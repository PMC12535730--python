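"""Admission cohorts: patient records, CSV ingestion/output, descriptive summaries.

A cohort is an ordered collection of :class:`PatientRecord` objects, one per
hospital admission for an acute COPD exacerbation.  Every clinical field
admits an explicit missing state (``None``); the in-hospital death flag never
does.  CSV files are plain UTF-8 with a header row; missing cells are written
as the empty string and read back as ``None`` (``NA``/``NaN`` sentinels are
accepted via :class:`CohortSchema`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortSchema",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "bun_mgdl_to_mmoll",
    "bun_mmoll_to_mgdl",
    "CLINICAL_FIELDS",
    "OUTCOME_FIELDS",
]

#: conversion factor for urea nitrogen: 1 mmol/L = 2.801 mg/dL
_BUN_MGDL_PER_MMOLL = 2.801


def bun_mgdl_to_mmoll(value: float) -> float:
    """Convert blood urea nitrogen from mg/dL to mmol/L."""
    return value / _BUN_MGDL_PER_MMOLL


def bun_mmoll_to_mgdl(value: float) -> float:
    """Convert blood urea nitrogen from mmol/L to mg/dL."""
    return value * _BUN_MGDL_PER_MMOLL


class CohortValidationError(ValueError):
    """Raised when a cohort file or record violates the schema invariants."""


@dataclass
class PatientRecord:
    """One admission's raw parameters, with explicit missingness.

    Continuous fields are ``None`` when not measured.  ``acidemia`` and
    ``eosinopenia`` may be supplied as precomputed flags; when the raw value
    (``ph``, ``eosinophils``) is also present, the raw value takes precedence
    at scoring time.
    """

    patient_id: str
    age: int | None = None                      # years
    sex: str | None = None                      # "male" | "female"
    heart_rate: float | None = None             # beats/min
    spo2: float | None = None                   # percent
    on_supplemental_o2: bool | None = None
    respiratory_rate: float | None = None       # breaths/min
    temperature: float | None = None            # degrees Celsius
    systolic_bp: float | None = None            # mmHg
    altered_mental_status: bool | None = None
    bun: float | None = None                    # blood urea nitrogen, mmol/L
    ph: float | None = None                     # arterial pH
    eosinophils: float | None = None            # 10^9 cells/L
    acidemia: bool | None = None                # flag path (pH < 7.30)
    eosinopenia: bool | None = None             # flag path (< 0.05 x 10^9/L)
    consolidation_cxr: bool | None = None
    atrial_fibrillation: bool | None = None
    death_inhospital: bool = False
    death_30d: bool | None = None
    icu_admission: bool | None = None
    los_days: float | None = None               # length of stay, days

    def replace(self, **changes) -> "PatientRecord":
        return dataclasses.replace(self, **changes)


_FIELD_ORDER = [f.name for f in fields(PatientRecord)]

#: physiologic plausibility ranges (inclusive), checked when a value is present
_RANGES: dict[str, tuple[float, float]] = {
    "age": (18, 120),
    "heart_rate": (1, 299),
    "spo2": (50, 100),
    "respiratory_rate": (1, 79),
    "temperature": (25, 43),
    "systolic_bp": (40, 300),
    "ph": (6.5, 8.0),
    "bun": (0, math.inf),
    "eosinophils": (0, math.inf),
    "los_days": (0, math.inf),
}

_FLAG_FIELDS = {
    "on_supplemental_o2",
    "altered_mental_status",
    "acidemia",
    "eosinopenia",
    "consolidation_cxr",
    "atrial_fibrillation",
    "death_inhospital",
    "death_30d",
    "icu_admission",
}
_INT_FIELDS = {"age"}
_FLOAT_FIELDS = {
    "heart_rate", "spo2", "respiratory_rate", "temperature",
    "systolic_bp", "bun", "ph", "eosinophils", "los_days",
}

#: clinical admission fields (may be missing; participate in summaries/imputation)
CLINICAL_FIELDS = [
    "age", "sex", "heart_rate", "spo2", "on_supplemental_o2",
    "respiratory_rate", "temperature", "systolic_bp",
    "altered_mental_status", "bun", "ph", "eosinophils",
    "acidemia", "eosinopenia", "consolidation_cxr", "atrial_fibrillation",
]
OUTCOME_FIELDS = ["death_inhospital", "death_30d", "icu_admission", "los_days"]


def validate_record(record: PatientRecord, row: int | str | None = None) -> None:
    """Check one record against the range/type invariants.

    Raises :class:`CohortValidationError` naming the offending row and field.
    """
    where = f"row {row}" if row is not None else f"patient {record.patient_id!r}"
    if not record.patient_id:
        raise CohortValidationError(f"{where}: empty patient_id")
    if record.death_inhospital is None:
        raise CohortValidationError(f"{where}: death_inhospital may not be missing")
    if record.sex is not None and record.sex not in ("male", "female"):
        raise CohortValidationError(f"{where}, field sex: {record.sex!r} not in {{male, female}}")
    for name, (lo, hi) in _RANGES.items():
        value = getattr(record, name)
        if value is None:
            continue
        if not (lo <= value <= hi):
            raise CohortValidationError(
                f"{where}, field {name}: value {value!r} outside [{lo}, {hi}]"
            )
    for name in _FLAG_FIELDS:
        value = getattr(record, name)
        if value is not None and not isinstance(value, bool):
            raise CohortValidationError(f"{where}, field {name}: {value!r} is not boolean")


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    records: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise CohortValidationError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def missingness(self) -> dict[str, float]:
        """Fraction of missing values per clinical field."""
        n = len(self.records)
        if n == 0:
            return {name: 0.0 for name in CLINICAL_FIELDS}
        return {
            name: sum(getattr(r, name) is None for r in self.records) / n
            for name in CLINICAL_FIELDS
        }

    def to_frame(self) -> pd.DataFrame:
        """Dataframe view; missing values become NaN/None, flags become 0/1."""
        rows = []
        for rec in self.records:
            row = {}
            for name in _FIELD_ORDER:
                value = getattr(rec, name)
                if name in _FLAG_FIELDS and value is not None:
                    value = int(value)
                row[name] = value
            rows.append(row)
        return pd.DataFrame(rows, columns=_FIELD_ORDER)


@dataclass
class CohortSchema:
    """Declares how a source CSV maps onto the canonical record fields.

    ``rename`` maps source header names to canonical field names;
    ``missing_values`` lists the cell sentinels treated as missing;
    ``bun_unit`` declares the unit of the BUN column ("mmol/L" or "mg/dL" —
    mg/dL inputs are converted on ingestion).
    """

    rename: dict[str, str] = field(default_factory=dict)
    missing_values: tuple[str, ...] = ("", "NA", "NaN", "nan")
    bun_unit: str = "mmol/L"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSchema":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            rename=dict(raw.get("rename", {})),
            missing_values=tuple(raw.get("missing_values", ("", "NA", "NaN", "nan"))),
            bun_unit=str(raw.get("bun_unit", "mmol/L")),
        )


_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n"}


def _parse_cell(name: str, text: str, where: str):
    if name == "patient_id":
        return text
    if name == "sex":
        return text.lower()
    if name in _FLAG_FIELDS:
        token = text.strip().lower()
        if token in _TRUE_TOKENS:
            return True
        if token in _FALSE_TOKENS:
            return False
        raise CohortValidationError(f"{where}, field {name}: {text!r} is not a flag value")
    try:
        if name in _INT_FIELDS:
            return int(float(text))
        return float(text)
    except ValueError:
        raise CohortValidationError(f"{where}, field {name}: cannot parse {text!r}") from None


def read_cohort(path: str | Path, schema: CohortSchema | None = None) -> Cohort:
    """Read a cohort CSV, validate it, and derive threshold flags.

    Missing cells (the schema's sentinels) become ``None``.  When raw pH or
    eosinophil values are present and the corresponding flag column is not,
    the acidemia/eosinopenia flags are derived using the score thresholds
    (pH < 7.30, eosinophils < 0.05 x 10^9/L).
    """
    schema = schema or CohortSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = frame.rename(columns=schema.rename)
    unknown = [c for c in frame.columns if c not in _FIELD_ORDER]
    if unknown:
        raise CohortValidationError(f"unknown column(s) {unknown} in {path.name}")
    if "patient_id" not in frame.columns:
        raise CohortValidationError(f"{path.name}: required column 'patient_id' not found")
    if "death_inhospital" not in frame.columns:
        raise CohortValidationError(f"{path.name}: required column 'death_inhospital' not found")

    sentinels = set(schema.missing_values)
    records: list[PatientRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        where = f"row {i}"
        kwargs: dict = {}
        for name, text in zip(frame.columns, row):
            if text in sentinels:
                continue
            kwargs[name] = _parse_cell(name, text, where)
        if "bun" in kwargs and schema.bun_unit == "mg/dL":
            kwargs["bun"] = bun_mgdl_to_mmoll(kwargs["bun"])
        rec = PatientRecord(**kwargs)
        if rec.acidemia is None and rec.ph is not None:
            rec.acidemia = rec.ph < 7.30
        if rec.eosinopenia is None and rec.eosinophils is not None:
            rec.eosinopenia = rec.eosinophils < 0.05
        validate_record(rec, row=i)
        records.append(rec)
    return Cohort(records, provenance=str(path))


def _format_cell(name: str, value) -> str:
    if value is None:
        return ""
    if name in _FLAG_FIELDS:
        return "1" if value else "0"
    if name in _INT_FIELDS:
        return str(int(value))
    if name in _FLOAT_FIELDS:
        return repr(float(value))  # repr round-trips exactly
    return str(value)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV; ``read_cohort`` of the result is the identity.

    Missing values are written as empty cells, flags as 0/1, floats with
    full (repr) precision so that values and missingness round-trip exactly.
    """
    path = Path(path)
    lines = [",".join(_FIELD_ORDER)]
    for rec in cohort.records:
        lines.append(",".join(_format_cell(n, getattr(rec, n)) for n in _FIELD_ORDER))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


_SUMMARY_CONTINUOUS = [
    "age", "heart_rate", "spo2", "respiratory_rate", "temperature",
    "systolic_bp", "bun", "ph", "eosinophils", "los_days",
]
_SUMMARY_BINARY = [
    "sex", "on_supplemental_o2", "altered_mental_status", "acidemia",
    "eosinopenia", "consolidation_cxr", "atrial_fibrillation",
    "death_inhospital", "death_30d", "icu_admission",
]


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Descriptive table: median [IQR] + mean for continuous fields, n (%)
    for categorical ones, and per-field missing %.

    Percentages use the non-missing count as denominator.  Both mean and
    median are reported for continuous fields.  Returns a dataframe indexed
    by field with columns ``kind, n_obs, missing_pct, mean, median, q1, q3,
    count, percent, formatted``.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    frame = cohort.to_frame()
    rows = []
    for name in _SUMMARY_CONTINUOUS:
        col = pd.to_numeric(frame[name], errors="coerce")
        obs = col.dropna()
        missing_pct = 100.0 * (n - len(obs)) / n
        if len(obs):
            rows.append({
                "field": name, "kind": "continuous", "n_obs": len(obs),
                "missing_pct": missing_pct,
                "mean": float(obs.mean()), "median": float(obs.median()),
                "q1": float(obs.quantile(0.25)), "q3": float(obs.quantile(0.75)),
                "count": float("nan"), "percent": float("nan"),
            })
        else:
            rows.append({
                "field": name, "kind": "continuous", "n_obs": 0,
                "missing_pct": missing_pct, "mean": float("nan"),
                "median": float("nan"), "q1": float("nan"), "q3": float("nan"),
                "count": float("nan"), "percent": float("nan"),
            })
    for name in _SUMMARY_BINARY:
        values = [getattr(r, name) for r in cohort.records]
        obs = [v for v in values if v is not None]
        missing_pct = 100.0 * (n - len(obs)) / n
        if name == "sex":
            count = sum(v == "male" for v in obs)
            label = "sex_male"
        else:
            count = sum(bool(v) for v in obs)
            label = name
        percent = 100.0 * count / len(obs) if obs else float("nan")
        rows.append({
            "field": label, "kind": "binary", "n_obs": len(obs),
            "missing_pct": missing_pct, "mean": float("nan"),
            "median": float("nan"), "q1": float("nan"), "q3": float("nan"),
            "count": float(count), "percent": percent,
        })
    out = pd.DataFrame(rows).set_index("field")
    out["formatted"] = [
        (f"{r['median']:.1f} [{r['q1']:.1f}, {r['q3']:.1f}]"
         if r["kind"] == "continuous" and r["n_obs"] > 0
         else f"{int(r['count'])} ({r['percent']:.1f}%)" if r["kind"] == "binary" and r["n_obs"] > 0
         else "–")
        for _, r in out.iterrows()
    ]
    return out
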