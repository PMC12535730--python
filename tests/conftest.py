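import numpy as np
import pytest

from copdrisk.cohort import Cohort, PatientRecord


@pytest.fixture
def worked_example_record() -> PatientRecord:
    """A typical moderate-risk admission used in the worked examples:
    74 y, HR 90, SpO2 92 on supplemental O2, RR 22, temp 36.5, SBP 138,
    alert, normal BUN/pH, eosinopenic, no consolidation, no AF."""
    return PatientRecord(
        patient_id="p1", age=74, sex="male", heart_rate=90, spo2=92,
        on_supplemental_o2=True, respiratory_rate=22, temperature=36.5,
        systolic_bp=138, altered_mental_status=False, bun=5.0, ph=7.40,
        eosinophils=0.03, consolidation_cxr=False, atrial_fibrillation=False,
    )


def make_record(pid: str = "p", **overrides) -> PatientRecord:
    """All-normal complete record; override individual fields per test."""
    base = dict(
        patient_id=pid, age=55, sex="female", heart_rate=70, spo2=97,
        on_supplemental_o2=False, respiratory_rate=16, temperature=37.0,
        systolic_bp=120, altered_mental_status=False, bun=5.0, ph=7.40,
        eosinophils=0.20, consolidation_cxr=False, atrial_fibrillation=False,
        death_inhospital=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


def random_complete_record(rng: np.random.Generator, pid: str) -> PatientRecord:
    """Uniform draw over the physiologic domain (for property tests)."""
    return PatientRecord(
        patient_id=pid,
        age=int(rng.integers(18, 101)),
        sex=str(rng.choice(["male", "female"])),
        heart_rate=float(rng.integers(20, 200)),
        spo2=float(rng.integers(60, 101)),
        on_supplemental_o2=bool(rng.integers(2)),
        respiratory_rate=float(rng.integers(4, 50)),
        temperature=float(np.round(rng.uniform(33.0, 41.5), 1)),
        systolic_bp=float(rng.integers(50, 260)),
        altered_mental_status=bool(rng.integers(2)),
        bun=float(np.round(rng.uniform(1.0, 25.0), 1)),
        ph=float(np.round(rng.uniform(6.9, 7.7), 2)),
        eosinophils=float(np.round(rng.uniform(0.0, 1.0), 3)),
        consolidation_cxr=bool(rng.integers(2)),
        atrial_fibrillation=bool(rng.integers(2)),
        death_inhospital=bool(rng.integers(2)),
    )


@pytest.fixture
def complete_cohort() -> Cohort:
    rng = np.random.default_rng(42)
    return Cohort([random_complete_record(rng, f"c{i}") for i in range(20)])
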