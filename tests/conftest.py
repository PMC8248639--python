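"""Shared fixtures: hand-built mini-cohorts and a default simulated cohort."""

from __future__ import annotations

import pandas as pd
import pytest

from pnsurv.cohort import (Cohort, INTERVIEW_COLUMNS, MATERNAL_COLUMNS,
                           NEWBORN_COLUMNS, coerce_interviews, coerce_maternal,
                           coerce_newborn, validate_cohort)
from pnsurv.simulate import SimulationConfig, simulate_cohort


def maternal_row(subject_id="W1", **kw) -> dict:
    row = dict.fromkeys(MATERNAL_COLUMNS)
    row.update(subject_id=subject_id, hospital="Amana", age_years=25,
               parity="1", delivery_mode="vaginal", case_note_available=1)
    row.update(kw)
    return row


def newborn_row(subject_id="W1", **kw) -> dict:
    row = dict.fromkeys(NEWBORN_COLUMNS)
    row.update(subject_id=subject_id, liveborn=1, apgar5=9,
               resuscitation_bag_mask=0, admission=0, documented_sepsis=0)
    row.update(kw)
    return row


def interview_row(subject_id="W1", wave="day7", interview_day=8, **kw) -> dict:
    row = dict.fromkeys(INTERVIEW_COLUMNS)
    row.update(subject_id=subject_id, wave=wave, reached=1,
               interview_day=interview_day, baby_alive=1)
    row.update(kw)
    return row


def build_cohort(maternal_rows, newborn_rows=None, interview_rows=None,
                 validate=True) -> Cohort:
    maternal = coerce_maternal(pd.DataFrame(maternal_rows, columns=list(MATERNAL_COLUMNS))
                               .astype(object).astype(str).replace({"None": None}))
    newborn_rows = newborn_rows if newborn_rows is not None else [
        newborn_row(r["subject_id"]) for r in maternal_rows]
    newborn = coerce_newborn(pd.DataFrame(newborn_rows, columns=list(NEWBORN_COLUMNS))
                             .astype(object).astype(str).replace({"None": None}))
    interview_rows = interview_rows or []
    interviews = coerce_interviews(
        pd.DataFrame(interview_rows, columns=list(INTERVIEW_COLUMNS))
        .astype(object).astype(str).replace({"None": None}))
    report = validate_cohort(maternal, newborn, interviews)
    if validate and report.errors:
        raise AssertionError([e.to_dict() for e in report.errors])
    return Cohort(maternal, newborn, interviews, report)


@pytest.fixture(scope="session")
def sim_cohort():
    """One default-configuration simulated cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=20180315))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Cohort with no background symptoms or case-note sepsis (oracle runs)."""
    cfg = SimulationConfig(seed=4242, background_symptom_rate=0.0,
                           p_documented_sepsis=0.0)
    return simulate_cohort(cfg)
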