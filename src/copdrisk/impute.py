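"""k-nearest-neighbor imputation of missing admission parameters.

Distances are Gower-type over pairwise-observed features: range-normalized
absolute difference for continuous fields, 0/1 mismatch for flags and sex,
averaged over the features both records have observed.  Continuous fields
are imputed by the median of the k nearest neighbors' observed values, flags
and sex by majority vote; all ties break deterministically by ascending
record index.  Outcome fields never participate in the distance, so the
imputation cannot leak the endpoint it will later be validated against.

Imputation operates on raw parameters (pH, eosinophils, ...), after which
scores are computed — not on score totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CLINICAL_FIELDS, Cohort, PatientRecord
from .scores import ACIDEMIA_PH, EOSINOPENIA_CELLS

__all__ = ["ImputationSpec", "ImputedCell", "knn_impute", "DEFAULT_FEATURES"]

#: raw clinical fields used both as distance features and imputation targets;
#: the acidemia/eosinopenia flag duplicates of pH/eosinophils are excluded so
#: a parameter never enters the distance twice
DEFAULT_FEATURES: tuple[str, ...] = (
    "age", "sex", "heart_rate", "spo2", "on_supplemental_o2",
    "respiratory_rate", "temperature", "systolic_bp",
    "altered_mental_status", "bun", "ph", "eosinophils",
    "consolidation_cxr", "atrial_fibrillation",
)

_CATEGORICAL = {
    "sex", "on_supplemental_o2", "altered_mental_status",
    "consolidation_cxr", "atrial_fibrillation", "acidemia", "eosinopenia",
}
_INTEGER = {"age"}


@dataclass
class ImputationSpec:
    """Configuration of the kNN imputer.

    k defaults to 10 neighbors; ``features`` lists the record fields that
    participate (as distance features and as imputation targets).
    """

    k: int = 10
    features: tuple[str, ...] = DEFAULT_FEATURES
    distance: str = "gower"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.distance != "gower":
            raise ValueError(f"unsupported distance {self.distance!r}")
        bad = [f for f in self.features if f not in CLINICAL_FIELDS]
        if bad:
            raise ValueError(f"non-clinical feature(s) in imputation spec: {bad}")


@dataclass
class ImputedCell:
    """Audit entry for one filled-in cell."""

    patient_id: str
    row: int
    field: str
    value: object
    neighbor_ids: list[str]


def _encode(cohort: Cohort, features: Sequence[str]) -> np.ndarray:
    """Matrix encoding: NaN = missing, flags/sex as 0/1, numerics as float."""
    n = len(cohort)
    X = np.full((n, len(features)), np.nan)
    for j, name in enumerate(features):
        for i, rec in enumerate(cohort):
            v = getattr(rec, name)
            if v is None:
                continue
            if name == "sex":
                X[i, j] = 1.0 if v == "male" else 0.0
            elif name in _CATEGORICAL:
                X[i, j] = float(bool(v))
            else:
                X[i, j] = float(v)
    return X


def _gower_matrix(X: np.ndarray, features: Sequence[str]) -> np.ndarray:
    """Pairwise Gower distances; inf where two records share no feature."""
    n = X.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j, name in enumerate(features):
        col = X[:, j]
        obs = ~np.isnan(col)
        pair = obs[:, None] & obs[None, :]
        if name in _CATEGORICAL:
            contrib = (col[:, None] != col[None, :]).astype(float)
        else:
            observed = col[obs]
            rng = float(observed.max() - observed.min()) if observed.size else 0.0
            if rng == 0.0:
                contrib = np.zeros((n, n))
            else:
                contrib = np.abs(col[:, None] - col[None, :]) / rng
        num += np.where(pair, contrib, 0.0)
        den += pair
    with np.errstate(invalid="ignore", divide="ignore"):
        D = num / den
    D[den == 0] = np.inf
    return D


def _decode(name: str, value: float):
    if name == "sex":
        return "male" if value >= 0.5 else "female"
    if name in _CATEGORICAL:
        return bool(round(value))
    if name in _INTEGER:
        return int(round(value))
    return float(value)


def knn_impute(cohort: Cohort, spec: ImputationSpec | None = None,
               return_report: bool = False):
    """Fill every missing participating field from the k nearest neighbors.

    Observed cells are never modified.  Each missing cell is filled from the
    k records nearest in Gower distance among those with that field
    observed — median for continuous fields, majority vote for flags and
    sex; ties (equal distance, or a split vote) resolve toward the
    lowest-index record.  Returns the imputed cohort, or
    ``(cohort, report)`` when ``return_report`` is true, where the report
    lists every imputed cell with its donor patient ids.
    """
    spec = spec or ImputationSpec()
    n = len(cohort)
    if spec.k >= n:
        raise ValueError(f"k={spec.k} must be smaller than the cohort size {n}")
    X = _encode(cohort, spec.features)
    observed = ~np.isnan(X)
    if not observed.any(axis=1).all():
        empty = [cohort[i].patient_id for i in np.where(~observed.any(axis=1))[0]]
        raise ValueError(f"record(s) with no observed feature: {empty}")
    short = [name for j, name in enumerate(spec.features)
             if 0 < (n - observed[:, j].sum()) and observed[:, j].sum() < spec.k]
    if short:
        raise ValueError(
            f"feature(s) observed in fewer than k={spec.k} records: {short}"
        )
    if observed.all():
        result_cohort = Cohort(list(cohort.records), provenance=cohort.provenance)
        return (result_cohort, []) if return_report else result_cohort

    D = _gower_matrix(X, spec.features)
    report: list[ImputedCell] = []
    new_records: list[PatientRecord] = []
    for i, rec in enumerate(cohort):
        changes: dict = {}
        for j, name in enumerate(spec.features):
            if observed[i, j]:
                continue
            donors = np.where(observed[:, j])[0]
            donors = donors[donors != i]
            order = donors[np.argsort(D[i, donors], kind="stable")]
            nearest = order[: spec.k]
            values = X[nearest, j]
            if name in _CATEGORICAL:
                # majority; exact split resolves to the lowest-index donor's value
                ones = values.sum()
                if ones * 2 == len(values):
                    imputed = values[0]
                else:
                    imputed = 1.0 if ones * 2 > len(values) else 0.0
            else:
                imputed = float(np.median(values))
            decoded = _decode(name, imputed)
            changes[name] = decoded
            report.append(ImputedCell(
                patient_id=rec.patient_id, row=i, field=name, value=decoded,
                neighbor_ids=[cohort[d].patient_id for d in nearest],
            ))
        # imputed raw labs refresh their threshold flags (raw takes precedence)
        if "ph" in changes and rec.acidemia is None:
            changes["acidemia"] = changes["ph"] < ACIDEMIA_PH
        if "eosinophils" in changes and rec.eosinopenia is None:
            changes["eosinopenia"] = changes["eosinophils"] < EOSINOPENIA_CELLS
        new_records.append(rec.replace(**changes) if changes else rec)
    out = Cohort(new_records, provenance=f"{cohort.provenance} [knn-imputed k={spec.k}]")
    return (out, report) if return_report else out
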