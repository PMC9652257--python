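"""Shared fixtures: record builders with clinically plausible defaults."""

from __future__ import annotations

import pytest
from hypothesis import settings

from liverdss import CohortTable, OutcomeRecord, PatientRecord, ResectionTarget

settings.register_profile("ci", settings(max_examples=100, derandomize=True, deadline=None))
settings.load_profile("ci")


def _make_target(**kwargs) -> ResectionTarget:
    defaults = dict(
        resection_type="wedge",
        segments=frozenset({"5"}),
        tumor_size_cm=2.0,
        malignant=False,
        proximity_major_vessels=False,
    )
    defaults.update(kwargs)
    return ResectionTarget(**defaults)


def _make_patient(**kwargs) -> PatientRecord:
    defaults = dict(
        patient_id="P001",
        age_years=60,
        sex="M",
        bmi=24.0,
        asa=2,
        child_pugh="A",
        platelets_1e9_per_L=200.0,
        portal_hypertension=False,
        liver_histology="healthy",
        previous_open_liver_resection=False,
        neoadjuvant_chemotherapy=False,
        comorb_cardiologic=False,
        comorb_vascular=False,
        comorb_diabetes=False,
        comorb_respiratory=False,
        comorb_neurologic=False,
        comorb_ckd=False,
        approach="pure_laparoscopic",
        resections=(_make_target(),),
    )
    defaults.update(kwargs)
    return PatientRecord(**defaults)


def _make_outcome(**kwargs) -> OutcomeRecord:
    defaults = dict(
        operative_time_min=180,
        blood_loss_ml=100,
        conversion=False,
        transfusion=False,
        satava_grade="none",
        clavien_dindo=0,
        los_days=4,
        margin="R0",
        readmission_90d=False,
        mortality_90d=False,
    )
    defaults.update(kwargs)
    return OutcomeRecord(**defaults)


@pytest.fixture
def make_target():
    return _make_target


@pytest.fixture
def make_patient():
    return _make_patient


@pytest.fixture
def make_outcome():
    return _make_outcome


@pytest.fixture
def small_cohort(make_patient, make_outcome) -> CohortTable:
    """Three patients spanning the difficulty range."""
    rows = [
        (
            make_patient(patient_id="A"),
            make_outcome(),
        ),
        (
            make_patient(
                patient_id="B",
                resections=(
                    _make_target(
                        resection_type="anatomical_segmentectomy",
                        segments=frozenset({"7"}),
                        tumor_size_cm=4.0,
                        malignant=True,
                    ),
                ),
            ),
            make_outcome(operative_time_min=250, los_days=7, clavien_dindo=1),
        ),
        (
            make_patient(
                patient_id="C",
                resections=(
                    _make_target(
                        resection_type="right_hepatectomy",
                        segments=frozenset({"5", "6", "7", "8"}),
                        tumor_size_cm=6.0,
                        malignant=True,
                        proximity_major_vessels=True,
                    ),
                ),
            ),
            make_outcome(
                operative_time_min=400,
                blood_loss_ml=800,
                conversion=True,
                satava_grade="II",
                clavien_dindo=3,
                los_days=12,
                margin="R1",
            ),
        ),
    ]
    return CohortTable(rows=rows, provenance="observed")
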