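"""Shared fixtures: hand-built micro-stays and generated cohorts."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from hapiphen.ehr_model import (
    ChartEvent,
    ClinicalNote,
    CohortStore,
    DiagnosisCode,
    HospitalStay,
    store_from_records,
)
from hapiphen.pi_text import KeywordLexicon
from hapiphen.synthetic import GeneratorParams, generate_cohort, store_from_tables

ADMIT = datetime(2130, 3, 1, 8, 0)


def make_stay(stay_id="S1", duration_hours=168.0, age=70.0, died=False,
              admit=ADMIT) -> HospitalStay:
    return HospitalStay(
        stay_id=stay_id, patient_id=f"P_{stay_id}", admit_ts=admit,
        discharge_ts=admit + timedelta(hours=duration_hours),
        died_in_hospital=died, age_at_admission=age)


def chart_at(stay: HospitalStay, hours: float, value: str, item_id="551") -> ChartEvent:
    return ChartEvent(stay.stay_id, stay.admit_ts + timedelta(hours=hours), item_id, value)


def note_at(stay: HospitalStay, hours: float, text: str, note_id=None,
            date_only=False) -> ClinicalNote:
    ts = stay.admit_ts + timedelta(hours=hours)
    if date_only:
        ts = ts.replace(hour=0, minute=0, second=0)
    return ClinicalNote(note_id or f"N{hours:g}", stay.stay_id, ts, "Nursing",
                        text, date_only)


def dx(stay: HospitalStay, code: str, seq=1) -> DiagnosisCode:
    return DiagnosisCode(stay.stay_id, code, seq)


def single_stay_store(stay, chart_events=(), notes=(), diagnoses=(),
                      procedures=()) -> CohortStore:
    return store_from_records([stay], chart_events=chart_events, notes=notes,
                              diagnoses=diagnoses, procedures=procedures)


@pytest.fixture
def lex() -> KeywordLexicon:
    return KeywordLexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort: 400 stays, mixed trajectories."""
    params = GeneratorParams(n_stays=400, seed=11)
    tables, gt = generate_cohort(params)
    return store_from_tables(tables), gt, params


@pytest.fixture(scope="session")
def separable_cohort():
    """Cohort whose case-stay notes carry a planted non-lexicon signal token."""
    params = GeneratorParams(n_stays=600, seed=7, target_prevalence=0.12,
                             signal_token="xylocarbine")
    tables, gt = generate_cohort(params)
    return store_from_tables(tables), gt, params
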