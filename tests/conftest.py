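"""Shared fixtures: the built-in ruleset and report-building helpers."""

from __future__ import annotations

from datetime import date, datetime, time, timedelta

import pytest

from sentinel.reports import DailyReport, PatientProfile, SymptomResponse
from sentinel.rules import Dimension, Phase, Ruleset, builtin_pancreas_ruleset

BASE_DATE = date(2021, 3, 1)  # a Monday


@pytest.fixture(scope="session")
def ruleset() -> Ruleset:
    return builtin_pancreas_ruleset()


def make_report(
    ruleset: Ruleset,
    patient_id: str,
    day: int,
    overrides: dict[str, dict] | None = None,
    phase: Phase = Phase.POST_SURGERY,
    base_date: date = BASE_DATE,
    submitted_time: time = time(10, 0),
) -> DailyReport:
    """A complete report for ``phase`` with all symptoms absent except
    ``overrides``: {symptom_id: {"frequency": 3}} marks the symptom present
    with the given follow-up codes (assessed follow-ups default to 1)."""
    overrides = overrides or {}
    responses = []
    for sym in ruleset.symptoms_for_phase(phase):
        ov = overrides.get(sym.symptom_id)
        if ov is None:
            responses.append(SymptomResponse(symptom_id=sym.symptom_id, occurrence=False))
            continue
        freq = dist = None
        if Dimension.FREQUENCY in sym.dimensions_assessed:
            freq = ov.get("frequency", 1)
        if Dimension.DISTRESS in sym.dimensions_assessed:
            dist = ov.get("distress", 1)
        responses.append(
            SymptomResponse(
                symptom_id=sym.symptom_id,
                occurrence=ov.get("occurrence", True),
                frequency=freq if ov.get("occurrence", True) else None,
                distress=dist if ov.get("occurrence", True) else None,
            )
        )
    report_date = base_date + timedelta(days=day)
    return DailyReport(
        patient_id=patient_id,
        report_date=report_date,
        submitted_at=datetime.combine(report_date, submitted_time),
        phase=phase,
        responses=tuple(responses),
    )


def make_profile(
    patient_id: str = "p001",
    n_days: int = 60,
    chemo_day: int | None = None,
    base_date: date = BASE_DATE,
) -> PatientProfile:
    return PatientProfile(
        patient_id=patient_id,
        reporting_start=base_date,
        reporting_end=base_date + timedelta(days=n_days - 1),
        chemo_start=base_date + timedelta(days=chemo_day) if chemo_day is not None else None,
    )
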