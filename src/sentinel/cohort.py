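"""Seeded synthetic cohort generator and the independent alert oracle.

The generator emulates daily ordinal symptom reporting: each symptom
follows a two-state Markov chain (onset/persistence) so that
consecutive-day windows can actually fire, days are missed i.i.d., and a
fraction of patients switches to the chemotherapy phase mid-stream.  A
truth log records, for every rule, exactly which patient-days qualified —
the raw material for the brute-force window-scan oracle used to verify the
streak engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np

from .reports import AdviceViewEvent, DailyReport, PatientProfile, SymptomResponse
from .rules import AlertRule, Dimension, Phase, Ruleset, Severity, builtin_pancreas_ruleset

__all__ = [
    "CohortParams",
    "CohortData",
    "TruthLog",
    "PatientTruth",
    "generate_cohort",
    "oracle_count_alerts",
    "oracle_alerts",
    "default_advice_map",
]

_BASE_DATE = date(2021, 1, 4)  # a Monday; per-patient offsets are added


@dataclass(frozen=True)
class CohortParams:
    """Knobs for the synthetic cohort.

    Defaults target the regimes of a six-month post-surgical monitoring
    study: follow-up 35-245 days, adherence mostly high but spread out.
    """

    n_patients: int = 26
    followup_days_range: tuple[int, int] = (35, 245)
    p_miss: float = 0.15
    chemo_fraction: float = 0.65
    chemo_start_day_range: tuple[int, int] = (30, 70)
    p_onset: float = 0.08
    p_persist: float = 0.6
    severity_dist: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    advice_view_rate: float = 0.3
    baseline_view_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("followup_days_range", "chemo_start_day_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be an ordered positive range")
        for name in ("p_miss", "chemo_fraction", "p_onset", "p_persist"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if len(self.severity_dist) != 4 or abs(sum(self.severity_dist) - 1.0) > 1e-9:
            raise ValueError("severity_dist must be 4 probabilities summing to 1")
        if self.advice_view_rate < 0 or self.baseline_view_rate < 0:
            raise ValueError("view rates must be non-negative")

    @classmethod
    def from_dict(cls, doc: dict) -> "CohortParams":
        kwargs = dict(doc)
        for key in ("followup_days_range", "chemo_start_day_range", "severity_dist"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class PatientTruth:
    """Ground truth for one patient: which days were reported, each day's
    phase, and per-rule qualifying days."""

    reported_dates: set[date] = field(default_factory=set)
    phase_by_date: dict[date, Phase] = field(default_factory=dict)
    qualifying: dict[str, set[date]] = field(default_factory=dict)


@dataclass
class TruthLog:
    patients: dict[str, PatientTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            pid: {
                "reported_dates": sorted(d.isoformat() for d in t.reported_dates),
                "phase_by_date": {
                    d.isoformat(): p.value for d, p in sorted(t.phase_by_date.items())
                },
                "qualifying": {
                    rule_id: sorted(d.isoformat() for d in dates)
                    for rule_id, dates in sorted(t.qualifying.items())
                },
            }
            for pid, t in sorted(self.patients.items())
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthLog":
        doc = json.loads(text)
        log = cls()
        for pid, entry in doc.items():
            log.patients[pid] = PatientTruth(
                reported_dates={date.fromisoformat(d) for d in entry["reported_dates"]},
                phase_by_date={
                    date.fromisoformat(d): Phase(p)
                    for d, p in entry["phase_by_date"].items()
                },
                qualifying={
                    rule_id: {date.fromisoformat(d) for d in dates}
                    for rule_id, dates in entry["qualifying"].items()
                },
            )
        return log


@dataclass
class CohortData:
    profiles: list[PatientProfile]
    reports: list[DailyReport]
    advice_views: list[AdviceViewEvent]
    truth_log: TruthLog


def default_advice_map(ruleset: Ruleset) -> dict[str, list[str]]:
    """One advice item per cataloged symptom."""
    return {s.symptom_id: [f"adv_{s.symptom_id}"] for s in ruleset.catalog}


def _qualifying_codes(rule: AlertRule, ruleset: Ruleset) -> set[int]:
    scale = ruleset.scales[rule.dimension]
    return {scale.code_for(label) for label in rule.qualifying_responses}


def generate_cohort(params: CohortParams, ruleset: Ruleset | None = None) -> CohortData:
    """Generate profiles, canonical reports, advice views, and the truth log.

    Deterministic given ``params.seed``; each patient draws from an
    independent substream keyed by (seed, patient index), so enlarging the
    cohort never perturbs existing patients.
    """
    if ruleset is None:
        ruleset = builtin_pancreas_ruleset()
    rule_codes = {r.rule_id: _qualifying_codes(r, ruleset) for r in ruleset.rules}
    all_symptoms = [s.symptom_id for s in ruleset.catalog]

    profiles: list[PatientProfile] = []
    reports: list[DailyReport] = []
    views: list[AdviceViewEvent] = []
    truth = TruthLog()

    for i in range(params.n_patients):
        rng = np.random.default_rng([params.seed, i])
        pid = f"p{i + 1:03d}"
        followup = int(
            rng.integers(params.followup_days_range[0], params.followup_days_range[1] + 1)
        )
        start = _BASE_DATE + timedelta(days=int(rng.integers(0, 60)))
        end = start + timedelta(days=followup - 1)
        chemo_start: date | None = None
        if rng.random() < params.chemo_fraction:
            lo, hi = params.chemo_start_day_range
            chemo_day = int(rng.integers(lo, hi + 1))
            if chemo_day < followup:
                chemo_start = start + timedelta(days=chemo_day)
        profiles.append(
            PatientProfile(
                patient_id=pid,
                reporting_start=start,
                reporting_end=end,
                chemo_start=chemo_start,
            )
        )

        ptruth = PatientTruth()
        truth.patients[pid] = ptruth
        occ_state = {sid: False for sid in all_symptoms}
        for day in range(followup):
            d = start + timedelta(days=day)
            phase = (
                Phase.CHEMOTHERAPY
                if chemo_start is not None and d >= chemo_start
                else Phase.POST_SURGERY
            )
            ptruth.phase_by_date[d] = phase
            # latent symptom states advance every calendar day
            day_codes: dict[str, tuple[bool, int | None, int | None]] = {}
            for sid in all_symptoms:
                p = params.p_persist if occ_state[sid] else params.p_onset
                occ_state[sid] = bool(rng.random() < p)
                freq = dist = None
                if occ_state[sid]:
                    freq = int(rng.choice(4, p=params.severity_dist)) + 1
                    dist = int(rng.choice(4, p=params.severity_dist)) + 1
                day_codes[sid] = (occ_state[sid], freq, dist)

            if rng.random() < params.p_miss:
                continue  # missed day: no report, no truth entries for rules
            ptruth.reported_dates.add(d)

            responses = []
            for sym in ruleset.symptoms_for_phase(phase):
                occ, freq, dist = day_codes[sym.symptom_id]
                responses.append(
                    SymptomResponse(
                        symptom_id=sym.symptom_id,
                        occurrence=occ,
                        frequency=(
                            freq if occ and Dimension.FREQUENCY in sym.dimensions_assessed else None
                        ),
                        distress=(
                            dist if occ and Dimension.DISTRESS in sym.dimensions_assessed else None
                        ),
                    )
                )
            submitted = datetime.combine(
                d, time(int(rng.integers(7, 22)), int(rng.integers(0, 60)))
            )
            reports.append(
                DailyReport(
                    patient_id=pid,
                    report_date=d,
                    submitted_at=submitted,
                    phase=phase,
                    responses=tuple(responses),
                )
            )

            # truth log: direct label-level check, no streak machinery
            resp_by_sid = {r.symptom_id: r for r in responses}
            for rule in ruleset.rules_for_phase(phase):
                resp = resp_by_sid.get(rule.symptom_id)
                if resp is None:
                    continue
                if rule.dimension is Dimension.OCCURRENCE:
                    value: int | None = 1 if resp.occurrence else 0
                elif rule.dimension is Dimension.FREQUENCY:
                    value = resp.frequency
                else:
                    value = resp.distress
                if value is not None and value in rule_codes[rule.rule_id]:
                    ptruth.qualifying.setdefault(rule.rule_id, set()).add(d)

            # advice views: symptom-linked browsing plus background browsing
            for sid, (occ, _, _) in day_codes.items():
                if occ and rng.random() < params.advice_view_rate:
                    views.append(
                        AdviceViewEvent(
                            patient_id=pid,
                            advice_id=f"adv_{sid}",
                            viewed_at=submitted + timedelta(minutes=int(rng.integers(1, 120))),
                        )
                    )
            if rng.random() < params.baseline_view_rate:
                sid = all_symptoms[int(rng.integers(0, len(all_symptoms)))]
                views.append(
                    AdviceViewEvent(
                        patient_id=pid,
                        advice_id=f"adv_{sid}",
                        viewed_at=submitted + timedelta(hours=2),
                    )
                )

    reports.sort(key=lambda r: (r.patient_id, r.report_date))
    views.sort(key=lambda v: (v.patient_id, v.viewed_at, v.advice_id))
    return CohortData(profiles=profiles, reports=reports, advice_views=views, truth_log=truth)


def oracle_alerts(
    truth_log: TruthLog,
    ruleset: Ruleset,
    red_supersedes_yellow: bool = True,
) -> set[tuple[str, str, date]]:
    """Brute-force window scan: the set of (patient, rule, date) alerts.

    For each rule and candidate date, an alert fires iff the trailing
    ``window_days`` dates were all reported, all in the rule's phase, and
    all qualifying.  This deliberately shares no state machinery with the
    streak engine.
    """
    fired: set[tuple[str, str, date]] = set()
    rules_by_id = {r.rule_id: r for r in ruleset.rules}
    for pid, ptruth in truth_log.patients.items():
        for rule_id, qdates in ptruth.qualifying.items():
            rule = rules_by_id[rule_id]
            for d in qdates:
                window = [d - timedelta(days=k) for k in range(rule.window_days)]
                ok = all(
                    w in ptruth.reported_dates
                    and ptruth.phase_by_date.get(w) is rule.phase
                    and w in qdates
                    for w in window
                )
                if ok:
                    fired.add((pid, rule_id, d))
    if red_supersedes_yellow:
        red_keys = {
            (pid, rules_by_id[rid].symptom_id, d)
            for pid, rid, d in fired
            if rules_by_id[rid].severity is Severity.RED
        }
        fired = {
            (pid, rid, d)
            for pid, rid, d in fired
            if rules_by_id[rid].severity is Severity.RED
            or (pid, rules_by_id[rid].symptom_id, d) not in red_keys
        }
    return fired


def oracle_count_alerts(
    truth_log: TruthLog,
    ruleset: Ruleset,
    red_supersedes_yellow: bool = True,
) -> dict[str, int]:
    """Per-rule alert counts from the brute-force oracle."""
    counts: dict[str, int] = {r.rule_id: 0 for r in ruleset.rules}
    for _, rule_id, _ in oracle_alerts(truth_log, ruleset, red_supersedes_yellow):
        counts[rule_id] += 1
    return counts
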