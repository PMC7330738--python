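"""Patients, daily symptom reports, advice-view events, and their file formats.

Raw submissions are canonicalized to exactly one report per patient-day
(latest submission wins) before they reach the alert engine or analytics.
Interchange formats are JSON-lines (one report per line, lossless nesting)
and a long CSV with one symptom response per row.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from datetime import date, datetime

from .rules import Dimension, Phase, Ruleset

__all__ = [
    "PatientProfile",
    "SymptomResponse",
    "DailyReport",
    "AdviceViewEvent",
    "ReportError",
    "canonicalize",
    "assign_phase",
    "validate_report",
    "reports_to_jsonl",
    "reports_from_jsonl",
    "reports_to_csv",
    "reports_from_csv",
    "profiles_to_csv",
    "profiles_from_csv",
    "advice_views_to_csv",
    "advice_views_from_csv",
]

STOP_REASONS = ("own_choice", "transferred", "death", "completed")


class ReportError(ValueError):
    """Raised for structurally invalid reports or profiles."""


@dataclass(frozen=True)
class PatientProfile:
    """Reporting window and optional chemotherapy start for one patient."""

    patient_id: str
    reporting_start: date
    reporting_end: date
    chemo_start: date | None = None
    stop_reason: str | None = None

    def __post_init__(self) -> None:
        if self.reporting_start > self.reporting_end:
            raise ReportError(
                f"patient {self.patient_id}: reporting_start after reporting_end"
            )
        if self.chemo_start is not None and not (
            self.reporting_start <= self.chemo_start <= self.reporting_end
        ):
            raise ReportError(
                f"patient {self.patient_id}: chemo_start outside reporting window"
            )
        if self.stop_reason is not None and self.stop_reason not in STOP_REASONS:
            raise ReportError(
                f"patient {self.patient_id}: unknown stop_reason {self.stop_reason!r}"
            )


@dataclass(frozen=True)
class SymptomResponse:
    """One symptom's answers within a daily report.

    Frequency/distress codes are present only when the symptom occurred and
    the dimension is assessed for that symptom.
    """

    symptom_id: str
    occurrence: bool
    frequency: int | None = None
    distress: int | None = None

    def __post_init__(self) -> None:
        if not self.occurrence and (self.frequency is not None or self.distress is not None):
            raise ReportError(
                f"{self.symptom_id}: frequency/distress given without occurrence"
            )
        for name, value in (("frequency", self.frequency), ("distress", self.distress)):
            if value is not None and not 1 <= value <= 4:
                raise ReportError(f"{self.symptom_id}: {name} code {value} out of range 1-4")


@dataclass(frozen=True)
class DailyReport:
    patient_id: str
    report_date: date
    submitted_at: datetime
    phase: Phase
    responses: tuple[SymptomResponse, ...]
    free_text: str | None = None


@dataclass(frozen=True)
class AdviceViewEvent:
    patient_id: str
    advice_id: str
    viewed_at: datetime


def assign_phase(profile: PatientProfile, report_date: date) -> Phase:
    """Phase of a report date: chemotherapy on and after ``chemo_start``,
    post-surgery otherwise.  The date must lie in the reporting window."""
    if not profile.reporting_start <= report_date <= profile.reporting_end:
        raise ReportError(
            f"patient {profile.patient_id}: date {report_date} outside reporting window"
        )
    if profile.chemo_start is not None and report_date >= profile.chemo_start:
        return Phase.CHEMOTHERAPY
    return Phase.POST_SURGERY


def canonicalize(
    raw_reports: list[DailyReport],
    profiles: dict[str, PatientProfile] | None = None,
) -> tuple[list[DailyReport], list[str]]:
    """Collapse raw submissions to one report per patient-day.

    The submission with the latest ``submitted_at`` wins (ties broken in
    favor of the later position is irrelevant: equal timestamps and equal
    content are indistinguishable; equal timestamps with different content
    are resolved deterministically by report ordering after sort).  Output
    is sorted by (patient_id, report_date).  When ``profiles`` is given,
    reports outside a patient's reporting window are dropped and a warning
    string is recorded; unknown patients are likewise rejected.

    Returns ``(canonical_reports, warnings)``.
    """
    warnings: list[str] = []
    kept: dict[tuple[str, date], DailyReport] = {}
    # Sort first so equal-timestamp conflicts resolve deterministically
    # regardless of input order.
    for report in sorted(
        raw_reports, key=lambda r: (r.patient_id, r.report_date, r.submitted_at)
    ):
        if profiles is not None:
            profile = profiles.get(report.patient_id)
            if profile is None:
                warnings.append(
                    f"report {report.patient_id}/{report.report_date}: unknown patient"
                )
                continue
            if not profile.reporting_start <= report.report_date <= profile.reporting_end:
                warnings.append(
                    f"report {report.patient_id}/{report.report_date}: "
                    "outside reporting window"
                )
                continue
        key = (report.patient_id, report.report_date)
        prev = kept.get(key)
        if prev is None or report.submitted_at >= prev.submitted_at:
            kept[key] = report
    canonical = [kept[k] for k in sorted(kept)]
    return canonical, warnings


def validate_report(report: DailyReport, ruleset: Ruleset) -> list[str]:
    """Return completeness/consistency problems for one report (empty = valid).

    Every symptom assessed in the report's phase must be answered, and
    frequency/distress must be present exactly when the symptom occurred
    and the dimension is assessed.
    """
    problems: list[str] = []
    expected = {s.symptom_id: s for s in ruleset.symptoms_for_phase(report.phase)}
    answered = {r.symptom_id for r in report.responses}
    for missing in sorted(set(expected) - answered):
        problems.append(f"missing response for {missing}")
    for resp in report.responses:
        sym = expected.get(resp.symptom_id)
        if sym is None:
            problems.append(f"unexpected symptom {resp.symptom_id} for phase {report.phase.value}")
            continue
        if resp.occurrence:
            for dim, value in (
                (Dimension.FREQUENCY, resp.frequency),
                (Dimension.DISTRESS, resp.distress),
            ):
                if dim in sym.dimensions_assessed and value is None:
                    problems.append(f"{resp.symptom_id}: {dim.value} not answered")
                if dim not in sym.dimensions_assessed and value is not None:
                    problems.append(f"{resp.symptom_id}: {dim.value} not assessed but answered")
    return problems


# ---------------------------------------------------------------------------
# serialization


def _report_to_obj(report: DailyReport) -> dict:
    return {
        "patient_id": report.patient_id,
        "report_date": report.report_date.isoformat(),
        "submitted_at": report.submitted_at.isoformat(),
        "phase": report.phase.value,
        "responses": [
            {
                "symptom_id": r.symptom_id,
                "occurrence": r.occurrence,
                "frequency": r.frequency,
                "distress": r.distress,
            }
            for r in report.responses
        ],
        "free_text": report.free_text,
    }


def _report_from_obj(obj: dict) -> DailyReport:
    return DailyReport(
        patient_id=str(obj["patient_id"]),
        report_date=date.fromisoformat(obj["report_date"]),
        submitted_at=datetime.fromisoformat(obj["submitted_at"]),
        phase=Phase(obj["phase"]),
        responses=tuple(
            SymptomResponse(
                symptom_id=str(r["symptom_id"]),
                occurrence=bool(r["occurrence"]),
                frequency=None if r.get("frequency") is None else int(r["frequency"]),
                distress=None if r.get("distress") is None else int(r["distress"]),
            )
            for r in obj["responses"]
        ),
        free_text=obj.get("free_text"),
    )


def reports_to_jsonl(reports: list[DailyReport]) -> str:
    return "".join(json.dumps(_report_to_obj(r), ensure_ascii=False) + "\n" for r in reports)


def reports_from_jsonl(text: str) -> list[DailyReport]:
    reports = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            reports.append(_report_from_obj(json.loads(line)))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ReportError(f"line {lineno}: bad report record: {exc}") from exc
    return reports


_CSV_COLUMNS = [
    "patient_id",
    "report_date",
    "submitted_at",
    "phase",
    "symptom_id",
    "occurrence",
    "frequency",
    "distress",
    "free_text",
]


def reports_to_csv(reports: list[DailyReport]) -> str:
    """Long-format CSV: one symptom response per row."""
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_CSV_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for report in reports:
        for resp in report.responses:
            writer.writerow(
                {
                    "patient_id": report.patient_id,
                    "report_date": report.report_date.isoformat(),
                    "submitted_at": report.submitted_at.isoformat(),
                    "phase": report.phase.value,
                    "symptom_id": resp.symptom_id,
                    "occurrence": int(resp.occurrence),
                    "frequency": "" if resp.frequency is None else resp.frequency,
                    "distress": "" if resp.distress is None else resp.distress,
                    "free_text": report.free_text or "",
                }
            )
    return buf.getvalue()


def reports_from_csv(text: str) -> list[DailyReport]:
    rows_by_key: dict[tuple[str, str, str], list[dict]] = {}
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or not set(_CSV_COLUMNS[:6]) <= set(reader.fieldnames):
        raise ReportError("reports CSV is missing required columns")
    for row in reader:
        key = (row["patient_id"], row["report_date"], row["submitted_at"])
        rows_by_key.setdefault(key, []).append(row)
    reports = []
    for (patient_id, report_date, submitted_at), rows in rows_by_key.items():
        try:
            responses = tuple(
                SymptomResponse(
                    symptom_id=row["symptom_id"],
                    occurrence=bool(int(row["occurrence"])),
                    frequency=int(row["frequency"]) if row.get("frequency") else None,
                    distress=int(row["distress"]) if row.get("distress") else None,
                )
                for row in rows
            )
            reports.append(
                DailyReport(
                    patient_id=patient_id,
                    report_date=date.fromisoformat(report_date),
                    submitted_at=datetime.fromisoformat(submitted_at),
                    phase=Phase(rows[0]["phase"]),
                    responses=responses,
                    free_text=rows[0].get("free_text") or None,
                )
            )
        except (KeyError, ValueError) as exc:
            raise ReportError(
                f"bad report rows for {patient_id}/{report_date}: {exc}"
            ) from exc
    reports.sort(key=lambda r: (r.patient_id, r.report_date, r.submitted_at))
    return reports


def profiles_to_csv(profiles: list[PatientProfile]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["patient_id", "reporting_start", "reporting_end", "chemo_start", "stop_reason"]
    )
    for p in profiles:
        writer.writerow(
            [
                p.patient_id,
                p.reporting_start.isoformat(),
                p.reporting_end.isoformat(),
                p.chemo_start.isoformat() if p.chemo_start else "",
                p.stop_reason or "",
            ]
        )
    return buf.getvalue()


def profiles_from_csv(text: str) -> list[PatientProfile]:
    profiles = []
    for row in csv.DictReader(io.StringIO(text)):
        try:
            profiles.append(
                PatientProfile(
                    patient_id=row["patient_id"],
                    reporting_start=date.fromisoformat(row["reporting_start"]),
                    reporting_end=date.fromisoformat(row["reporting_end"]),
                    chemo_start=(
                        date.fromisoformat(row["chemo_start"]) if row.get("chemo_start") else None
                    ),
                    stop_reason=row.get("stop_reason") or None,
                )
            )
        except (KeyError, ValueError) as exc:
            raise ReportError(f"bad profile row {row!r}: {exc}") from exc
    return profiles


def advice_views_to_csv(views: list[AdviceViewEvent]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["patient_id", "advice_id", "viewed_at"])
    for v in views:
        writer.writerow([v.patient_id, v.advice_id, v.viewed_at.isoformat()])
    return buf.getvalue()


def advice_views_from_csv(text: str) -> list[AdviceViewEvent]:
    views = []
    for row in csv.DictReader(io.StringIO(text)):
        try:
            views.append(
                AdviceViewEvent(
                    patient_id=row["patient_id"],
                    advice_id=row["advice_id"],
                    viewed_at=datetime.fromisoformat(row["viewed_at"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ReportError(f"bad advice-view row {row!r}: {exc}") from exc
    return views
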