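"""Streak-based alert evaluation of canonical daily reports.

Each rule keeps a run-length of calendar-consecutive qualifying days.  A
missed day (no report) breaks every streak, because an unreported day is
unknown and a safety system must not assume persistence.  An alert is
emitted whenever a rule's run length reaches its window; by default the
rule re-fires on every further day the condition keeps holding
("daily" policy), with a once-per-episode alternative behind a switch.
When a red and a yellow rule for the same symptom both fire on the same
report, only the red alert is emitted — one phone call is made either
way — but the yellow streak still advances.
"""

from __future__ import annotations

import csv
import hashlib
import io
import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta

from .reports import DailyReport, PatientProfile, SymptomResponse
from .rules import AlertRule, Dimension, Phase, RatingScale, Ruleset, Severity

__all__ = [
    "StreakState",
    "Alert",
    "EnginePolicy",
    "response_qualifies",
    "evaluate_report",
    "run_timeline",
    "suggest_advice",
    "alerts_to_csv",
    "alerts_from_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class StreakState:
    """Run-length tracker for one rule.

    ``run_length`` is zero exactly when ``last_qualifying_date`` is unset;
    it increments only when the next qualifying report is dated exactly one
    day after the previous one.
    """

    rule_id: str
    run_length: int = 0
    last_qualifying_date: date | None = None


@dataclass(frozen=True)
class Alert:
    alert_id: str
    patient_id: str
    rule_id: str
    symptom_id: str
    severity: Severity
    trigger_date: date
    triggered_at: datetime
    streak_length_at_trigger: int


@dataclass(frozen=True)
class EnginePolicy:
    """Engine behavior switches.

    retrigger: "daily" re-fires a rule on every day its window is satisfied;
    "episode" fires only on the first day a streak reaches the window.
    """

    retrigger: str = "daily"
    red_supersedes_yellow: bool = True

    def __post_init__(self) -> None:
        if self.retrigger not in ("daily", "episode"):
            raise ValueError(f"unknown retrigger policy {self.retrigger!r}")


def _alert_id(patient_id: str, rule_id: str, trigger_date: date) -> str:
    # Deterministic so reruns produce identical ledgers.
    digest = hashlib.sha1(f"{patient_id}|{rule_id}|{trigger_date.isoformat()}".encode())
    return digest.hexdigest()[:12]


def response_qualifies(
    rule: AlertRule,
    response: SymptomResponse,
    scales: dict[Dimension, RatingScale],
) -> bool:
    """True iff the response's rated value maps to a qualifying label.

    Occurrence rules compare the boolean against the occurrence scale's
    labels ("Yes"/"No" by default); frequency and distress compare the
    stored code's label.  A response without the rated dimension (symptom
    absent, or follow-up not answered) never qualifies.
    """
    if response.symptom_id != rule.symptom_id:
        raise ValueError(
            f"response for {response.symptom_id} evaluated against rule for {rule.symptom_id}"
        )
    scale = scales[rule.dimension]
    if rule.dimension is Dimension.OCCURRENCE:
        label = scale.label_for(1 if response.occurrence else 0)
        return label in rule.qualifying_responses
    code = response.frequency if rule.dimension is Dimension.FREQUENCY else response.distress
    if code is None:
        return False
    return scale.label_for(code) in rule.qualifying_responses


def evaluate_report(
    report: DailyReport,
    ruleset: Ruleset,
    state: dict[str, StreakState],
    policy: EnginePolicy = EnginePolicy(),
) -> tuple[list[Alert], dict[str, StreakState]]:
    """Evaluate one canonical report; returns emitted alerts and new state.

    Streak updates per phase-matching rule: increment when qualifying and
    date-consecutive with the previous qualifying day; restart at 1 when
    qualifying after a gap; reset to 0 when not qualifying.  The input
    state is not mutated.
    """
    responses = {r.symptom_id: r for r in report.responses}
    new_state: dict[str, StreakState] = {
        k: StreakState(v.rule_id, v.run_length, v.last_qualifying_date)
        for k, v in state.items()
    }
    candidates: list[Alert] = []
    for rule in ruleset.rules_for_phase(report.phase):
        streak = new_state.setdefault(rule.rule_id, StreakState(rule.rule_id))
        response = responses.get(rule.symptom_id)
        qualifies = response is not None and response_qualifies(
            rule, response, ruleset.scales
        )
        if qualifies:
            if streak.last_qualifying_date == report.report_date - timedelta(days=1):
                streak.run_length += 1
            else:
                streak.run_length = 1
            streak.last_qualifying_date = report.report_date
        else:
            streak.run_length = 0
            streak.last_qualifying_date = None
            continue
        fires = (
            streak.run_length >= rule.window_days
            if policy.retrigger == "daily"
            else streak.run_length == rule.window_days
        )
        if fires:
            candidates.append(
                Alert(
                    alert_id=_alert_id(report.patient_id, rule.rule_id, report.report_date),
                    patient_id=report.patient_id,
                    rule_id=rule.rule_id,
                    symptom_id=rule.symptom_id,
                    severity=rule.severity,
                    trigger_date=report.report_date,
                    triggered_at=report.submitted_at,
                    streak_length_at_trigger=streak.run_length,
                )
            )
    if policy.red_supersedes_yellow:
        red_symptoms = {a.symptom_id for a in candidates if a.severity is Severity.RED}
        candidates = [
            a
            for a in candidates
            if a.severity is Severity.RED or a.symptom_id not in red_symptoms
        ]
    return candidates, new_state


def run_timeline(
    patient: PatientProfile,
    reports: list[DailyReport],
    ruleset: Ruleset,
    policy: EnginePolicy = EnginePolicy(),
) -> list[Alert]:
    """Fold :func:`evaluate_report` over a patient's canonical, sorted reports.

    Streaks are cleared at the phase switch: rule identities differ across
    phases and the chemotherapy panel has no multi-day windows.
    """
    alerts: list[Alert] = []
    state: dict[str, StreakState] = {}
    current_phase: Phase | None = None
    for report in reports:
        if report.patient_id != patient.patient_id:
            continue
        if current_phase is not None and report.phase is not current_phase:
            state = {}
        current_phase = report.phase
        emitted, state = evaluate_report(report, ruleset, state, policy)
        alerts.extend(emitted)
    return alerts


def suggest_advice(alerts: list[Alert], advice_map: dict[str, list[str]]) -> list[str]:
    """Deduplicated, stable-ordered advice ids for the alerting symptoms.

    Symptoms missing from ``advice_map`` are skipped with a warning.
    """
    suggested: list[str] = []
    seen: set[str] = set()
    for alert in alerts:
        advice_ids = advice_map.get(alert.symptom_id)
        if advice_ids is None:
            logger.warning("no advice mapped for symptom %s", alert.symptom_id)
            continue
        if isinstance(advice_ids, str):  # tolerate a single id
            advice_ids = [advice_ids]
        for advice_id in advice_ids:
            if advice_id not in seen:
                seen.add(advice_id)
                suggested.append(advice_id)
    return suggested


_ALERT_COLUMNS = [
    "alert_id",
    "patient_id",
    "symptom_id",
    "rule_id",
    "severity",
    "trigger_date",
    "triggered_at",
    "streak_length",
]


def alerts_to_csv(alerts: list[Alert]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_ALERT_COLUMNS)
    for a in alerts:
        writer.writerow(
            [
                a.alert_id,
                a.patient_id,
                a.symptom_id,
                a.rule_id,
                a.severity.value,
                a.trigger_date.isoformat(),
                a.triggered_at.isoformat(),
                a.streak_length_at_trigger,
            ]
        )
    return buf.getvalue()


def alerts_from_csv(text: str) -> list[Alert]:
    alerts = []
    for row in csv.DictReader(io.StringIO(text)):
        alerts.append(
            Alert(
                alert_id=row["alert_id"],
                patient_id=row["patient_id"],
                rule_id=row["rule_id"],
                symptom_id=row["symptom_id"],
                severity=Severity(row["severity"]),
                trigger_date=date.fromisoformat(row["trigger_date"]),
                triggered_at=datetime.fromisoformat(row["triggered_at"]),
                streak_length_at_trigger=int(row["streak_length"]),
            )
        )
    return alerts
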