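"""Shared fixtures: a small simulated cohort and a hand-built patient factory."""
from __future__ import annotations

import warnings

import pytest

import ipwmsm as m

warnings.filterwarnings("ignore", category=UserWarning)


DEFAULT_COV = {
    "age": 72.0, "female": 1, "af": 0, "chd": 0, "diabetes": 0,
    "heart_failure": 0, "hypertension": 1, "smoking": "never", "bmi": 26.0,
    "imd": 3, "subtype": "ischaemic", "consultations": 25,
}


def make_patient(pid=0, rx=(), events=(), death=None, transfer=None,
                 reg=1000, linked=True, deter=None, **cov):
    """Hand-built patient record; rx entries are days (30-day supply) or (day, supply)."""
    rx = [(r, 30) if isinstance(r, int) else tuple(r) for r in rx]
    covariates = dict(DEFAULT_COV)
    covariates.update(cov)
    return m.PatientRecord(
        patient_id=pid, registration_start=reg, covariates=covariates,
        prescriptions=rx, events=list(events), death_day=death,
        transfer_day=transfer, linked=linked, deterioration_day=deter,
    )


@pytest.fixture()
def patient_factory():
    return make_patient


@pytest.fixture(scope="session")
def small_cfg():
    return m.SimulationConfig(n_patients=3000, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return m.generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_eligible(small_cohort):
    eligible, _ = m.apply_eligibility(small_cohort)
    return eligible


@pytest.fixture(scope="session")
def small_intervals(small_eligible):
    return m.build_person_intervals(small_eligible, "ITT")
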