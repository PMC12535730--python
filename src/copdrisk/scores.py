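"""Deterministic score calculators: NEWS, BAP-65 class, DECAFm, AECOPD-COMBI.

Four admission risk scores for hospitalized COPD exacerbations:

* **NEWS** (0–20): banded points over six vital-sign parameters plus a
  consciousness item.  Here the consciousness item is derived from the binary
  altered-mental-status field (alert → 0, otherwise → 3), a documented
  dialect of NEWS for cohorts that record mental status as a flag rather
  than the four-level AVPU scale.
* **BAP-65** (class I–V, reported 1–5): risk factors are elevated blood urea
  nitrogen (≥ 8.9 mmol/L), altered mental status, and pulse > 109/min
  (implemented as heart rate ≥ 110, identical on integers); age ≥ 65 splits
  the zero-factor classes.
* **DECAFm** (0–4): one point each for eosinopenia (< 0.05 × 10⁹/L),
  consolidation on chest X-ray, acidemia (pH < 7.30) and atrial
  fibrillation.  The dyspnea (eMRCD) item of the original DECAF is omitted.
* **AECOPD-COMBI** (0–51): a composite summing rescaled contributions of the
  three scores so each origin can contribute at most 16–18 points
  (BAP-65 binaries × 6, NEWS vital bands × 1, DECAFm items × 4); parameters
  shared between scores (heart rate, mental status) are counted once, with
  the more granular banding kept.

Band edges are taken at the published printed precision: measurements are
rounded (half-even) to that precision before lookup — temperature to one
decimal, all other banded vitals to integers — which makes the bands
exhaustive over the physiologic input domain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord

__all__ = [
    "IncompleteScoreError",
    "news_points",
    "compute_news",
    "compute_bap65",
    "compute_decafm",
    "compute_combi",
    "score_cohort",
    "origin_max_contributions",
    "NewsResult",
    "Bap65Result",
    "DecafmResult",
    "CombiResult",
    "ScoringResult",
    "SCORE_NAMES",
    "SCORE_DEPENDENCIES",
]

logger = logging.getLogger(__name__)

_INF = math.inf

SCORE_NAMES = ("bap65", "decafm", "news", "combi")


class IncompleteScoreError(ValueError):
    """A score's contributing field is missing; the score is not computable."""

    def __init__(self, score: str, missing: list[str]):
        self.score = score
        self.missing = missing
        super().__init__(f"{score}: missing input(s) {missing}")


# ---------------------------------------------------------------------------
# band tables (inclusive lower/upper bounds at printed precision)

#: NEWS vital-sign bands; points per (low, high) inclusive band
NEWS_BANDS: dict[str, list[tuple[float, float, int]]] = {
    "heart_rate": [
        (-_INF, 40, 3), (41, 50, 1), (51, 90, 0),
        (91, 110, 1), (111, 130, 2), (131, _INF, 3),
    ],
    "spo2": [(-_INF, 91, 3), (92, 93, 2), (94, 95, 1), (96, _INF, 0)],
    "respiratory_rate": [
        (-_INF, 8, 3), (9, 11, 1), (12, 20, 0), (21, 24, 2), (25, _INF, 3),
    ],
    "temperature": [
        (-_INF, 35.0, 3), (35.1, 36.0, 1), (36.1, 38.0, 0),
        (38.1, 39.0, 1), (39.1, _INF, 2),
    ],
    "systolic_bp": [
        (-_INF, 90, 3), (91, 100, 2), (101, 110, 1), (111, 219, 0), (220, _INF, 3),
    ],
}

#: printed precision per banded parameter (decimals); default integer
_BAND_DECIMALS = {"temperature": 1}

#: thresholds for the binary items
BUN_ELEVATED_MMOLL = 8.9
ACIDEMIA_PH = 7.30
EOSINOPENIA_CELLS = 0.05
BAP65_AGE_CUTOFF = 65
BAP65_PULSE_CUTOFF = 110  # "pulse > 109"

#: composite weights per score of origin
COMBI_WEIGHTS = {"bap65": 6, "news": 1, "decafm": 4}

#: origin of every composite parameter (shared parameters counted once,
#: with heart rate kept under NEWS — the more granular banding — and mental
#: status under BAP-65)
COMBI_ORIGIN: dict[str, str] = {
    "age": "bap65",
    "heart_rate": "news",
    "spo2": "news",
    "on_supplemental_o2": "news",
    "respiratory_rate": "news",
    "temperature": "news",
    "systolic_bp": "news",
    "altered_mental_status": "bap65",
    "bun": "bap65",
    "acidemia": "decafm",
    "eosinopenia": "decafm",
    "consolidation_cxr": "decafm",
    "atrial_fibrillation": "decafm",
}


def _round_to_band(parameter: str, value: float) -> float:
    decimals = _BAND_DECIMALS.get(parameter, 0)
    return float(np.round(value, decimals))  # round-half-even


def news_points(parameter: str, value) -> int:
    """Points for one NEWS parameter.

    Banded vitals are rounded (half-even) to the printed band precision and
    looked up; ``on_supplemental_o2`` and ``consciousness`` (altered mental
    status) are boolean items worth 2 and 3 points respectively.
    """
    if value is None:
        raise IncompleteScoreError("news", [parameter])
    if parameter == "on_supplemental_o2":
        return 2 if value else 0
    if parameter in ("consciousness", "altered_mental_status"):
        return 3 if value else 0
    if parameter not in NEWS_BANDS:
        raise KeyError(f"unknown NEWS parameter {parameter!r}")
    rounded = _round_to_band(parameter, float(value))
    for low, high, points in NEWS_BANDS[parameter]:
        if low <= rounded <= high:
            return points
    raise ValueError(f"{parameter}={value!r} escaped the band table")  # pragma: no cover


@dataclass
class NewsResult:
    total: int
    components: dict[str, int]


@dataclass
class Bap65Result:
    risk_class: int          # 1..5
    risk_factors: int        # 0..3
    factors: dict[str, bool]


@dataclass
class DecafmResult:
    total: int
    components: dict[str, bool]


@dataclass
class CombiResult:
    total: int
    components: dict[str, int]


def _require(record: PatientRecord, score: str, names: list[str]) -> None:
    missing = [n for n in names if getattr(record, n) is None]
    if missing:
        raise IncompleteScoreError(score, missing)


def _resolve_acidemia(record: PatientRecord) -> bool | None:
    if record.ph is not None:
        return record.ph < ACIDEMIA_PH
    return record.acidemia


def _resolve_eosinopenia(record: PatientRecord) -> bool | None:
    if record.eosinophils is not None:
        return record.eosinophils < EOSINOPENIA_CELLS
    return record.eosinopenia


def _resolve_elevated_bun(record: PatientRecord) -> bool | None:
    if record.bun is None:
        return None
    if record.bun == BUN_ELEVATED_MMOLL:
        logger.info(
            "patient %s: BUN exactly at the 8.9 mmol/L cutoff; scored as elevated",
            record.patient_id,
        )
    return record.bun >= BUN_ELEVATED_MMOLL


#: fields each score needs (with either member of a raw/flag pair accepted)
SCORE_DEPENDENCIES: dict[str, list[str]] = {
    "news": ["heart_rate", "spo2", "on_supplemental_o2", "respiratory_rate",
             "temperature", "systolic_bp", "altered_mental_status"],
    "bap65": ["bun", "altered_mental_status", "heart_rate", "age"],
    "decafm": ["acidemia|ph", "eosinopenia|eosinophils",
               "consolidation_cxr", "atrial_fibrillation"],
}
SCORE_DEPENDENCIES["combi"] = sorted(
    set(SCORE_DEPENDENCIES["news"]) | set(SCORE_DEPENDENCIES["bap65"])
    | set(SCORE_DEPENDENCIES["decafm"])
)


def _has_dependency(record: PatientRecord, dep: str) -> bool:
    return any(getattr(record, alt) is not None for alt in dep.split("|"))


def score_is_computable(record: PatientRecord, score: str) -> bool:
    """True when every input the score needs is observed (raw or flag)."""
    return all(_has_dependency(record, d) for d in SCORE_DEPENDENCIES[score])


def compute_news(record: PatientRecord) -> NewsResult:
    """National Early Warning Score with a binary consciousness dialect."""
    vitals = ["heart_rate", "spo2", "on_supplemental_o2", "respiratory_rate",
              "temperature", "systolic_bp"]
    _require(record, "news", vitals + ["altered_mental_status"])
    components = {name: news_points(name, getattr(record, name)) for name in vitals}
    components["consciousness"] = 3 if record.altered_mental_status else 0
    return NewsResult(total=sum(components.values()), components=components)


def compute_bap65(record: PatientRecord) -> Bap65Result:
    """BAP-65 risk class (1–5) from BUN, mental status, pulse, and age."""
    _require(record, "bap65", ["bun", "altered_mental_status", "heart_rate", "age"])
    factors = {
        "elevated_bun": bool(_resolve_elevated_bun(record)),
        "altered_mental_status": bool(record.altered_mental_status),
        "pulse_gt_109": record.heart_rate >= BAP65_PULSE_CUTOFF,
    }
    count = sum(factors.values())
    if count == 0:
        risk_class = 2 if record.age >= BAP65_AGE_CUTOFF else 1
    else:
        risk_class = count + 2
    return Bap65Result(risk_class=risk_class, risk_factors=count, factors=factors)


def compute_decafm(record: PatientRecord) -> DecafmResult:
    """DECAF without the dyspnea item: one point per present component."""
    components = {
        "eosinopenia": _resolve_eosinopenia(record),
        "consolidation": record.consolidation_cxr,
        "acidemia": _resolve_acidemia(record),
        "atrial_fibrillation": record.atrial_fibrillation,
    }
    missing = [k for k, v in components.items() if v is None]
    if missing:
        raise IncompleteScoreError("decafm", missing)
    components = {k: bool(v) for k, v in components.items()}
    return DecafmResult(total=sum(components.values()), components=components)


def _combi_age_points(age: float) -> int:
    if age < 41:
        # composite's lowest printed band starts at 41 (BAP-65 targets > 40y)
        logger.warning("age %s below the score's derivation range (41+); scored 0", age)
        return 0
    return 6 if age >= BAP65_AGE_CUTOFF else 0


def compute_combi(record: PatientRecord) -> CombiResult:
    """AECOPD-COMBI composite (0–51) by direct point-table lookup."""
    deps = ["age", "heart_rate", "spo2", "on_supplemental_o2", "respiratory_rate",
            "temperature", "systolic_bp", "altered_mental_status", "bun"]
    _require(record, "combi", deps)
    acidemia = _resolve_acidemia(record)
    eosinopenia = _resolve_eosinopenia(record)
    missing = [name for name, value in
               [("acidemia", acidemia), ("eosinopenia", eosinopenia),
                ("consolidation_cxr", record.consolidation_cxr),
                ("atrial_fibrillation", record.atrial_fibrillation)]
               if value is None]
    if missing:
        raise IncompleteScoreError("combi", missing)
    components = {
        "age": _combi_age_points(record.age),
        "heart_rate": news_points("heart_rate", record.heart_rate),
        "spo2": news_points("spo2", record.spo2),
        "on_supplemental_o2": 2 if record.on_supplemental_o2 else 0,
        "respiratory_rate": news_points("respiratory_rate", record.respiratory_rate),
        "temperature": news_points("temperature", record.temperature),
        "systolic_bp": news_points("systolic_bp", record.systolic_bp),
        "altered_mental_status": 6 if record.altered_mental_status else 0,
        "bun": 6 if _resolve_elevated_bun(record) else 0,
        "acidemia": 4 if acidemia else 0,
        "eosinopenia": 4 if eosinopenia else 0,
        "consolidation_cxr": 4 if record.consolidation_cxr else 0,
        "atrial_fibrillation": 4 if record.atrial_fibrillation else 0,
    }
    return CombiResult(total=sum(components.values()), components=components)


def origin_max_contributions() -> dict[str, int]:
    """Maximum points each contributing score can add to the composite.

    Derived from the point table itself: per-parameter band maxima summed by
    score of origin.  The construction rescales the three scores so these
    maxima are approximately equal (17 ± 1).
    """
    param_max = {
        "age": 6,
        "on_supplemental_o2": 2,
        "altered_mental_status": 6,
        "bun": 6,
        "acidemia": 4,
        "eosinopenia": 4,
        "consolidation_cxr": 4,
        "atrial_fibrillation": 4,
    }
    for name, bands in NEWS_BANDS.items():
        param_max[name] = max(points for _, _, points in bands)
    out = {origin: 0 for origin in COMBI_WEIGHTS}
    for name, origin in COMBI_ORIGIN.items():
        out[origin] += param_max[name]
    return out


# ---------------------------------------------------------------------------
# cohort-level scoring

@dataclass
class ScoringResult:
    """Score panel plus the per-score count of patients with missing inputs."""

    panel: pd.DataFrame
    missing_counts: dict[str, int]
    policy: str


def score_cohort(cohort: Cohort, policy: str = "imputed",
                 imputation=None) -> ScoringResult:
    """Compute all four scores for every patient in the cohort.

    ``policy="imputed"`` first fills missing raw parameters with the
    k-nearest-neighbor imputer (``imputation`` overrides the default
    :class:`~copdrisk.impute.ImputationSpec`); ``policy="complete_only"``
    leaves missing inputs alone, so a score is emitted only for patients with
    every contributing field observed (the sensitivity-analysis convention).

    ``missing_counts`` always refers to the raw, pre-imputation cohort — the
    number of patients for whom each score could not be computed from
    observed data alone.
    """
    if policy not in ("imputed", "complete_only"):
        raise ValueError(f"unknown scoring policy {policy!r}")
    missing_counts = {
        score: sum(not score_is_computable(rec, score) for rec in cohort)
        for score in SCORE_NAMES
    }
    working = cohort
    if policy == "imputed" and any(v > 0 for v in cohort.missingness().values()):
        from .impute import ImputationSpec, knn_impute
        spec = imputation or ImputationSpec()
        working = knn_impute(cohort, spec)

    rows = []
    for rec in working:
        row: dict = {"patient_id": rec.patient_id}
        try:
            news = compute_news(rec)
            row["news_total"] = news.total
            for k, v in news.components.items():
                row[f"news_{k}"] = v
            row["news_complete"] = True
        except IncompleteScoreError:
            row["news_total"] = np.nan
            row["news_complete"] = False
        try:
            bap = compute_bap65(rec)
            row["bap65_class"] = bap.risk_class
            row["bap65_risk_factors"] = bap.risk_factors
            row["bap65_complete"] = True
        except IncompleteScoreError:
            row["bap65_class"] = np.nan
            row["bap65_risk_factors"] = np.nan
            row["bap65_complete"] = False
        try:
            dec = compute_decafm(rec)
            row["decafm_total"] = dec.total
            for k, v in dec.components.items():
                row[f"decafm_{k}"] = int(v)
            row["decafm_complete"] = True
        except IncompleteScoreError:
            row["decafm_total"] = np.nan
            row["decafm_complete"] = False
        try:
            combi = compute_combi(rec)
            row["combi_total"] = combi.total
            for k, v in combi.components.items():
                row[f"combi_{k}"] = v
            row["combi_complete"] = True
        except IncompleteScoreError:
            row["combi_total"] = np.nan
            row["combi_complete"] = False
        row["death_inhospital"] = int(rec.death_inhospital)
        rows.append(row)
    panel = pd.DataFrame(rows)
    return ScoringResult(panel=panel, missing_counts=missing_counts, policy=policy)
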