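"""Synthetic admission cohorts for testing the scoring and validation stack.

The generator draws each admission parameter independently from a marginal
distribution matched to a published cohort profile of hospitalized COPD
exacerbations (median/IQR/range for continuous vitals and labs, prevalence
for binary findings), then links in-hospital death to the patient's *true*
composite risk score through a logistic model

    P(death) = expit(alpha + beta * S),

where S is the AECOPD-COMBI total computed on the complete record.  The
intercept alpha is calibrated by root-finding so the cohort's expected
mortality matches a target rate (2.2% by default).  Missingness is applied
afterwards, per field, completely at random at configurable rates.

Every field draws from its own counter-derived random stream, so adding a
field to the configuration never perturbs the draws of existing fields.

The generator emulates the marginal structure and missingness pattern of a
real admission cohort; it makes no attempt to copy the (unreported) joint
correlation structure between parameters, so absolute discrimination levels
of the simulated scores are a property of the simulation, not of any real
cohort.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import optimize, stats
from scipy.special import expit, logit

from .cohort import Cohort, PatientRecord
from .scores import compute_combi

__all__ = [
    "ContinuousMarginal",
    "BinaryMarginal",
    "SimulationConfig",
    "SimulationTruth",
    "default_config",
    "generate_cohort",
    "apply_missingness",
    "simulate_cohort",
    "calibrate_intercept",
]

_IQR_TO_SIGMA = 2.0 * stats.norm.ppf(0.75)  # 1.349: IQR of a normal in sigmas


@dataclass
class ContinuousMarginal:
    """Truncated location–scale family matched to (median, IQR, range).

    ``family`` is ``"normal"`` (sigma = IQR/1.349) or ``"lognormal"``
    (sigma_log on the log scale, for right-skewed labs).  ``decimals``
    rounds draws to the measurement's recording precision.
    """

    family: str
    median: float
    iqr: float | None = None          # normal family
    sigma_log: float | None = None    # lognormal family
    low: float = -np.inf
    high: float = np.inf
    decimals: int = 0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            mu, sigma = self.median, self.iqr / _IQR_TO_SIGMA
            a, b = (self.low - mu) / sigma, (self.high - mu) / sigma
            x = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)
        elif self.family == "lognormal":
            mu, sigma = np.log(self.median), self.sigma_log
            lo = np.log(self.low) if self.low > 0 else -np.inf
            hi = np.log(self.high) if np.isfinite(self.high) else np.inf
            a, b = (lo - mu) / sigma, (hi - mu) / sigma
            x = np.exp(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n,
                                           random_state=rng))
        else:
            raise ValueError(f"unknown family {self.family!r}")
        return np.round(x, self.decimals)


@dataclass
class BinaryMarginal:
    prevalence: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        return rng.random(n) < self.prevalence


@dataclass
class SimulationConfig:
    """Cohort size, marginals, missingness rates and the outcome model."""

    n: int = 314
    seed: int = 0
    marginals: dict = field(default_factory=dict)
    missingness: dict = field(default_factory=dict)
    beta: float = 0.2                  # log-odds of death per composite point
    alpha: float | None = None         # None -> calibrated to target_mortality
    target_mortality: float = 0.022
    target_mortality_30d: float = 0.054
    target_icu: float = 0.172

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("cohort size must be >= 4")
        for name, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0, 1]")


def default_config(n: int = 314, seed: int = 0, **overrides) -> SimulationConfig:
    """Study-profile defaults.

    Continuous marginals reproduce the published admission profile
    (age median 74 IQR [67, 80] range [48, 94]; heart rate 90 [78, 103];
    SpO2 92.5 [88, 95]; respiratory rate 22 [20, 26]; systolic BP 138
    [122, 155]); spreads of BUN, pH and eosinophils are back-solved from the
    printed exceedance prevalences (elevated BUN 2.6%, acidemia 12.7%,
    eosinopenia 38.6%), and temperature from the fever prevalence (11.1% at
    >= 38 degrees C).  Binary prevalences: male 53.2%, supplemental O2 44.4%,
    altered mental status 7.1%, consolidation 17.9%, atrial fibrillation
    20.7%.  Missingness rates follow the per-field missing-percentage column
    of the same profile; in-hospital mortality is calibrated to 2.2%.
    """
    marginals = {
        "age": ContinuousMarginal("normal", 74, iqr=13, low=48, high=94),
        "heart_rate": ContinuousMarginal("normal", 90, iqr=25, low=40, high=180),
        "spo2": ContinuousMarginal("normal", 92.5, iqr=7, low=70, high=100),
        "respiratory_rate": ContinuousMarginal("normal", 22, iqr=6, low=8, high=50),
        "temperature": ContinuousMarginal("normal", 37.0, iqr=1.08, low=34, high=41,
                                          decimals=1),
        "systolic_bp": ContinuousMarginal("normal", 138, iqr=33, low=70, high=230),
        "bun": ContinuousMarginal("lognormal", 5.5, sigma_log=0.25, low=1, high=30,
                                  decimals=1),
        "ph": ContinuousMarginal("normal", 7.40, iqr=0.119, low=7.0, high=7.7,
                                 decimals=2),
        "eosinophils": ContinuousMarginal("lognormal", 0.08, sigma_log=1.6,
                                          low=0.001, high=10, decimals=3),
        "los_days": ContinuousMarginal("lognormal", 6, sigma_log=0.6, low=1, high=60,
                                       decimals=0),
        "sex_male": BinaryMarginal(0.532),
        "on_supplemental_o2": BinaryMarginal(0.444),
        "altered_mental_status": BinaryMarginal(0.071),
        "consolidation_cxr": BinaryMarginal(0.179),
        "atrial_fibrillation": BinaryMarginal(0.207),
    }
    missingness = {
        "heart_rate": 0.003,
        "on_supplemental_o2": 0.003,
        "respiratory_rate": 0.076,
        "temperature": 0.067,
        "systolic_bp": 0.013,
        "altered_mental_status": 0.010,
        "bun": 0.032,
        "ph": 0.271,
        "eosinophils": 0.159,
        "consolidation_cxr": 0.038,
    }
    return SimulationConfig(n=n, seed=seed, marginals=marginals,
                            missingness=missingness, **overrides)


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated cohort: seed, outcome model, true
    composite scores and the complete (pre-missingness) records."""

    seed: int
    alpha: float
    beta: float
    true_scores: np.ndarray
    death_probability: np.ndarray
    complete_cohort: Cohort


def _field_rng(seed: int, name: str) -> np.random.Generator:
    # per-field stream keyed by a name hash: adding a field never shifts others
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def calibrate_intercept(beta: float, target: float, scores) -> float:
    """Intercept alpha with mean(expit(alpha + beta*S)) = target over the sample.

    Solved by monotone root-finding (the mean is strictly increasing in
    alpha); exact closed form logit(target) when beta = 0.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target mortality must be in (0, 1)")
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("score sample is empty")
    if beta == 0.0:
        return float(logit(target))

    def gap(a: float) -> float:
        return float(expit(a + beta * s).mean() - target)

    lo, hi = -50.0, 50.0 - beta * (s.min() if beta > 0 else s.max())
    lo = min(lo, -50.0 - beta * (s.max() if beta > 0 else s.min()))
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("cannot bracket the calibration root")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, SimulationTruth]:
    """Draw n complete records and the score-linked in-hospital outcome.

    All clinical fields are present in the returned cohort (apply
    missingness separately); the death flag is Bernoulli in the true
    composite score.  The acidemia/eosinopenia flags are derived from the
    generated pH/eosinophil values so both ingestion paths stay consistent.
    """
    n, seed = config.n, config.seed
    draws: dict[str, np.ndarray] = {}
    for name, marginal in config.marginals.items():
        draws[name] = marginal.sample(n, _field_rng(seed, name))

    records: list[PatientRecord] = []
    width = len(str(n))
    for i in range(n):
        records.append(PatientRecord(
            patient_id=f"sim-{i:0{width}d}",
            age=int(draws["age"][i]),
            sex="male" if draws["sex_male"][i] else "female",
            heart_rate=float(draws["heart_rate"][i]),
            spo2=float(draws["spo2"][i]),
            on_supplemental_o2=bool(draws["on_supplemental_o2"][i]),
            respiratory_rate=float(draws["respiratory_rate"][i]),
            temperature=float(draws["temperature"][i]),
            systolic_bp=float(draws["systolic_bp"][i]),
            altered_mental_status=bool(draws["altered_mental_status"][i]),
            bun=float(draws["bun"][i]),
            ph=float(draws["ph"][i]),
            eosinophils=float(draws["eosinophils"][i]),
            acidemia=bool(draws["ph"][i] < 7.30),
            eosinopenia=bool(draws["eosinophils"][i] < 0.05),
            consolidation_cxr=bool(draws["consolidation_cxr"][i]),
            atrial_fibrillation=bool(draws["atrial_fibrillation"][i]),
        ))

    true_scores = np.array([compute_combi(rec).total for rec in records], dtype=float)
    alpha = (config.alpha if config.alpha is not None
             else calibrate_intercept(config.beta, config.target_mortality, true_scores))
    p_death = expit(alpha + config.beta * true_scores)
    death = _field_rng(seed, "death_inhospital").random(n) < p_death

    # secondary outcomes: same score link, calibrated to their own rates;
    # 30-day death is forced to contain in-hospital death
    alpha_30d = calibrate_intercept(config.beta, config.target_mortality_30d,
                                    true_scores)
    death_30d = (_field_rng(seed, "death_30d").random(n)
                 < expit(alpha_30d + config.beta * true_scores)) | death
    alpha_icu = calibrate_intercept(config.beta, config.target_icu, true_scores)
    icu = _field_rng(seed, "icu_admission").random(n) < expit(
        alpha_icu + config.beta * true_scores)

    complete = []
    for i, rec in enumerate(records):
        complete.append(rec.replace(
            death_inhospital=bool(death[i]),
            death_30d=bool(death_30d[i]),
            icu_admission=bool(icu[i]),
            los_days=float(draws["los_days"][i]),
        ))
    cohort = Cohort(complete, provenance=f"simulated(seed={seed}, n={n})")
    truth = SimulationTruth(seed=seed, alpha=float(alpha), beta=config.beta,
                            true_scores=true_scores, death_probability=p_death,
                            complete_cohort=cohort)
    return cohort, truth


_MASKABLE = {
    "age", "sex", "heart_rate", "spo2", "on_supplemental_o2",
    "respiratory_rate", "temperature", "systolic_bp", "altered_mental_status",
    "bun", "ph", "eosinophils", "acidemia", "eosinopenia",
    "consolidation_cxr", "atrial_fibrillation",
}
#: raw value and its threshold flag are masked together
_LINKED_FLAGS = {"ph": "acidemia", "eosinophils": "eosinopenia"}


def apply_missingness(cohort: Cohort, rates: Mapping[str, float],
                      seed: int) -> Cohort:
    """Mask clinical cells independently, field by field, at the given rates.

    Outcome fields are never masked.  Masking a raw lab value also masks its
    derived threshold flag (they carry the same measurement).
    """
    for name, rate in rates.items():
        if name not in _MASKABLE:
            raise ValueError(f"cannot apply missingness to field {name!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {name!r} outside [0, 1]")
    n = len(cohort)
    masks = {name: _field_rng(seed, f"missing:{name}").random(n) < rate
             for name, rate in rates.items()}
    new_records = []
    for i, rec in enumerate(cohort):
        changes: dict = {}
        for name, mask in masks.items():
            if mask[i]:
                changes[name] = None
                if name in _LINKED_FLAGS:
                    changes[_LINKED_FLAGS[name]] = None
        new_records.append(rec.replace(**changes) if changes else rec)
    return Cohort(new_records, provenance=f"{cohort.provenance} [masked]")


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SimulationTruth]:
    """Complete draw plus configured missingness: the full study input."""
    complete, truth = generate_cohort(config)
    masked = apply_missingness(complete, config.missingness,
                               seed=config.seed + 1 if config.seed < 2**31 - 1 else 0)
    return masked, truth
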