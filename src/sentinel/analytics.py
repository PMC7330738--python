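"""Adherence and descriptive cohort summaries from canonical reports,
alert ledgers, and advice-view logs.

All percentages use half-up rounding at a caller-chosen number of
decimals.  Frequency/distress means pool responses across patients by
default; a per-patient-mean variant is available via ``mode``.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .engine import Alert
from .reports import AdviceViewEvent, DailyReport, PatientProfile
from .rules import Ruleset, Severity

__all__ = [
    "AdherenceResult",
    "SymptomSummaryRow",
    "AlertSummaryRow",
    "AdviceSummaryRow",
    "pct",
    "adherence",
    "symptom_summary",
    "alert_summary",
    "advice_summary",
    "symptom_summary_frame",
    "alert_summary_frame",
    "advice_summary_frame",
]


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100*n/d with half-up rounding at ``decimals`` places.

    Half-up (not banker's) rounding matches hand arithmetic on printed
    counts, e.g. pct(182, 512, 1) == 35.5.
    """
    if denominator == 0:
        raise ZeroDivisionError("pct: zero denominator")
    if decimals < 0:
        raise ValueError("pct: decimals must be >= 0")
    exact = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AdherenceResult:
    patient_id: str
    days_reported: int
    days_expected: int
    adherence_pct: float


def adherence(profile: PatientProfile, reports: Iterable[DailyReport]) -> AdherenceResult:
    """Days with a submitted report over days the patient was meant to
    report (the inclusive reporting window), as a one-decimal percentage."""
    days_expected = (profile.reporting_end - profile.reporting_start).days + 1
    if days_expected <= 0:
        raise ValueError(f"patient {profile.patient_id}: empty reporting window")
    days_reported = len(
        {r.report_date for r in reports if r.patient_id == profile.patient_id}
    )
    return AdherenceResult(
        patient_id=profile.patient_id,
        days_reported=days_reported,
        days_expected=days_expected,
        adherence_pct=pct(days_reported, days_expected, 1),
    )


@dataclass(frozen=True)
class SymptomSummaryRow:
    symptom_id: str
    n_patients_reporting: int
    occurrence_count: int
    occurrence_pct_of_total: float
    per_patient_count_median: float | None
    per_patient_count_range: tuple[int, int] | None
    frequency_mean: float | None
    frequency_sd: float | None
    frequency_range: tuple[int, int] | None
    distress_mean: float | None
    distress_sd: float | None
    distress_range: tuple[int, int] | None


def _mean_sd_range(values: list[int]) -> tuple[float | None, float | None, tuple[int, int] | None]:
    if not values:
        return None, None, None
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return mean, sd, (min(values), max(values))


def symptom_summary(
    reports: list[DailyReport],
    ruleset: Ruleset,
    mode: str = "pooled",
    pct_decimals: int = 2,
) -> list[SymptomSummaryRow]:
    """One row per cataloged symptom, sorted by occurrence count descending.

    ``occurrence_count`` is the number of patient-days on which the symptom
    occurred; percentages are shares of the grand total of occurrences.
    ``mode`` selects how frequency/distress means are formed: "pooled"
    averages all occurrence-positive responses across patients;
    "per_patient" averages each patient's mean.
    """
    if mode not in ("pooled", "per_patient"):
        raise ValueError(f"unknown mode {mode!r}")
    per_symptom: dict[str, dict] = {
        s.symptom_id: {
            "patients": set(),
            "count_by_patient": {},
            "frequency": {},  # patient -> list of codes
            "distress": {},
        }
        for s in ruleset.catalog
    }
    for report in reports:
        for resp in report.responses:
            slot = per_symptom.get(resp.symptom_id)
            if slot is None or not resp.occurrence:
                continue
            slot["patients"].add(report.patient_id)
            slot["count_by_patient"][report.patient_id] = (
                slot["count_by_patient"].get(report.patient_id, 0) + 1
            )
            if resp.frequency is not None:
                slot["frequency"].setdefault(report.patient_id, []).append(resp.frequency)
            if resp.distress is not None:
                slot["distress"].setdefault(report.patient_id, []).append(resp.distress)

    total = sum(
        sum(slot["count_by_patient"].values()) for slot in per_symptom.values()
    )

    def dim_stats(by_patient: dict[str, list[int]]):
        pooled = [v for vs in by_patient.values() for v in vs]
        if not pooled:
            return None, None, None
        if mode == "pooled":
            mean, sd, rng = _mean_sd_range(pooled)
        else:
            patient_means = [statistics.fmean(vs) for vs in by_patient.values()]
            mean = statistics.fmean(patient_means)
            sd = statistics.stdev(patient_means) if len(patient_means) > 1 else 0.0
            rng = (min(pooled), max(pooled))
        return mean, sd, rng

    rows = []
    for symptom_id, slot in per_symptom.items():
        counts = list(slot["count_by_patient"].values())
        occurrence_count = sum(counts)
        f_mean, f_sd, f_rng = dim_stats(slot["frequency"])
        d_mean, d_sd, d_rng = dim_stats(slot["distress"])
        rows.append(
            SymptomSummaryRow(
                symptom_id=symptom_id,
                n_patients_reporting=len(slot["patients"]),
                occurrence_count=occurrence_count,
                occurrence_pct_of_total=(
                    pct(occurrence_count, total, pct_decimals) if total else 0.0
                ),
                per_patient_count_median=statistics.median(counts) if counts else None,
                per_patient_count_range=(min(counts), max(counts)) if counts else None,
                frequency_mean=f_mean,
                frequency_sd=f_sd,
                frequency_range=f_rng,
                distress_mean=d_mean,
                distress_sd=d_sd,
                distress_range=d_rng,
            )
        )
    rows.sort(key=lambda r: (-r.occurrence_count, r.symptom_id))
    return rows


@dataclass(frozen=True)
class AlertSummaryRow:
    symptom_id: str
    n_patients_alerting: int
    per_patient_alert_median: float
    per_patient_alert_range: tuple[int, int]
    red_count: int
    yellow_count: int


def alert_summary(alerts: list[Alert]) -> list[AlertSummaryRow]:
    """Per-symptom alert tallies with per-patient median (range)."""
    by_symptom: dict[str, list[Alert]] = {}
    for a in alerts:
        by_symptom.setdefault(a.symptom_id, []).append(a)
    rows = []
    for symptom_id, group in by_symptom.items():
        per_patient: dict[str, int] = {}
        for a in group:
            per_patient[a.patient_id] = per_patient.get(a.patient_id, 0) + 1
        counts = list(per_patient.values())
        rows.append(
            AlertSummaryRow(
                symptom_id=symptom_id,
                n_patients_alerting=len(per_patient),
                per_patient_alert_median=statistics.median(counts),
                per_patient_alert_range=(min(counts), max(counts)),
                red_count=sum(1 for a in group if a.severity is Severity.RED),
                yellow_count=sum(1 for a in group if a.severity is Severity.YELLOW),
            )
        )
    rows.sort(key=lambda r: (-r.n_patients_alerting, r.symptom_id))
    return rows


@dataclass(frozen=True)
class AdviceSummaryRow:
    advice_id: str
    n_patients_viewing: int
    view_count: int


def advice_summary(
    views: list[AdviceViewEvent],
    top: int | None = None,
    bottom: int | None = None,
) -> list[AdviceSummaryRow]:
    """Per-advice view counts; optionally restrict to the ``top``/``bottom``
    k items by view count."""
    by_advice: dict[str, list[AdviceViewEvent]] = {}
    for v in views:
        by_advice.setdefault(v.advice_id, []).append(v)
    rows = [
        AdviceSummaryRow(
            advice_id=advice_id,
            n_patients_viewing=len({v.patient_id for v in group}),
            view_count=len(group),
        )
        for advice_id, group in by_advice.items()
    ]
    rows.sort(key=lambda r: (-r.view_count, r.advice_id))
    if top is not None or bottom is not None:
        selected = []
        if top:
            selected.extend(rows[:top])
        if bottom:
            tail = rows[-bottom:] if bottom <= len(rows) else rows
            selected.extend(r for r in tail if r not in selected)
        rows = selected
    return rows


# --- DataFrame views for CSV export ---------------------------------------


def symptom_summary_frame(rows: list[SymptomSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "symptom_id": r.symptom_id,
                "n_patients_reporting": r.n_patients_reporting,
                "occurrence_count": r.occurrence_count,
                "occurrence_pct_of_total": r.occurrence_pct_of_total,
                "per_patient_count_median": r.per_patient_count_median,
                "per_patient_count_min": r.per_patient_count_range[0] if r.per_patient_count_range else None,
                "per_patient_count_max": r.per_patient_count_range[1] if r.per_patient_count_range else None,
                "frequency_mean": r.frequency_mean,
                "frequency_sd": r.frequency_sd,
                "distress_mean": r.distress_mean,
                "distress_sd": r.distress_sd,
            }
            for r in rows
        ]
    )


def alert_summary_frame(rows: list[AlertSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "symptom_id": r.symptom_id,
                "n_patients_alerting": r.n_patients_alerting,
                "per_patient_alert_median": r.per_patient_alert_median,
                "per_patient_alert_min": r.per_patient_alert_range[0],
                "per_patient_alert_max": r.per_patient_alert_range[1],
                "red_count": r.red_count,
                "yellow_count": r.yellow_count,
            }
            for r in rows
        ]
    )


def advice_summary_frame(rows: list[AdviceSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "advice_id": r.advice_id,
                "n_patients_viewing": r.n_patients_viewing,
                "view_count": r.view_count,
            }
            for r in rows
        ]
    )
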