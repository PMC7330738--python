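"""Working-hours contact scheduling for triggered alerts.

Red alerts demand contact within one hour, yellow alerts the same working
day.  Alerts submitted outside working hours (8 am to 4 pm on non-weekend
days by default) are deferred: the clinic is notified at the start of the
next working day and the clock starts there.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import yaml

from .engine import Alert
from .rules import Severity

__all__ = ["WorkCalendar", "ContactTask", "schedule_contact", "contacts_to_csv", "contacts_from_csv"]


@dataclass(frozen=True)
class WorkCalendar:
    """Clinic availability: daily working hours, weekend days, extra holidays.

    ``weekend_days`` uses Python weekday numbers (Monday=0 .. Sunday=6).
    """

    work_start: time = time(8, 0)
    work_end: time = time(16, 0)
    weekend_days: frozenset[int] = frozenset({5, 6})
    holidays: frozenset[date] = frozenset()

    def __post_init__(self) -> None:
        if self.work_start >= self.work_end:
            raise ValueError("work_start must precede work_end")
        if len(self.weekend_days) >= 7:
            raise ValueError("calendar has no working days")

    def is_working_day(self, d: date) -> bool:
        return d.weekday() not in self.weekend_days and d not in self.holidays

    def within_working_hours(self, ts: datetime) -> bool:
        return (
            self.is_working_day(ts.date())
            and self.work_start <= ts.time() < self.work_end
        )

    def next_working_day(self, d: date) -> date:
        nxt = d + timedelta(days=1)
        while not self.is_working_day(nxt):
            nxt += timedelta(days=1)
        return nxt

    @classmethod
    def from_yaml(cls, text: str) -> "WorkCalendar":
        doc = yaml.safe_load(text) or {}
        return cls(
            work_start=time.fromisoformat(str(doc.get("work_start", "08:00"))),
            work_end=time.fromisoformat(str(doc.get("work_end", "16:00"))),
            weekend_days=frozenset(int(d) for d in doc.get("weekend_days", [5, 6])),
            holidays=frozenset(date.fromisoformat(str(d)) for d in doc.get("holidays", [])),
        )


@dataclass(frozen=True)
class ContactTask:
    alert_id: str
    severity: Severity
    notify_at: datetime
    contact_deadline: datetime
    deferred: bool


def schedule_contact(alert: Alert, submitted_at: datetime, cal: WorkCalendar) -> ContactTask:
    """Compute when the clinic is notified and the contact deadline.

    Within working hours the clinic is notified immediately: red deadline
    is one hour later, clipped to the end of the working day (same-day
    contact is the outer bound the workflow supports); yellow deadline is
    the end of the working day.  Outside working hours notification waits
    for the next working day's start, the task is marked deferred, and the
    deadlines are computed from that notification instant.
    """
    if cal.within_working_hours(submitted_at):
        notify_at = submitted_at
        deferred = False
    else:
        deferred = True
        d = submitted_at.date()
        if cal.is_working_day(d) and submitted_at.time() < cal.work_start:
            notify_day = d
        else:
            notify_day = cal.next_working_day(d)
        notify_at = datetime.combine(notify_day, cal.work_start)
    day_end = datetime.combine(notify_at.date(), cal.work_end)
    if alert.severity is Severity.RED:
        deadline = min(notify_at + timedelta(hours=1), day_end)
    else:
        deadline = day_end
    return ContactTask(
        alert_id=alert.alert_id,
        severity=alert.severity,
        notify_at=notify_at,
        contact_deadline=deadline,
        deferred=deferred,
    )


def contacts_to_csv(tasks: list[ContactTask]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["alert_id", "severity", "notify_at", "contact_deadline", "deferred"])
    for t in tasks:
        writer.writerow(
            [
                t.alert_id,
                t.severity.value,
                t.notify_at.isoformat(),
                t.contact_deadline.isoformat(),
                int(t.deferred),
            ]
        )
    return buf.getvalue()


def contacts_from_csv(text: str) -> list[ContactTask]:
    tasks = []
    for row in csv.DictReader(io.StringIO(text)):
        tasks.append(
            ContactTask(
                alert_id=row["alert_id"],
                severity=Severity(row["severity"]),
                notify_at=datetime.fromisoformat(row["notify_at"]),
                contact_deadline=datetime.fromisoformat(row["contact_deadline"]),
                deferred=bool(int(row["deferred"])),
            )
        )
    return tasks
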