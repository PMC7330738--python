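"""Symptom catalog, rating scales, and the phase-dependent alert ruleset.

The ruleset is the clinical rule document at the heart of the monitoring
workflow: each rule maps (symptom, rated dimension, qualifying response
labels, consecutive-day window) to an alert severity, separately for the
post-surgery and chemotherapy care phases.  A built-in ruleset for
pancreatic-surgery follow-up is shipped as a YAML document and loaded
through the same code path as user-supplied configs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import yaml

__all__ = [
    "Phase",
    "Dimension",
    "Severity",
    "RatingScale",
    "SymptomDefinition",
    "AlertRule",
    "Ruleset",
    "RulesetError",
    "load_ruleset",
    "serialize_ruleset",
    "builtin_pancreas_ruleset",
    "default_scales",
]


class Phase(str, enum.Enum):
    """Care phase a report (and rule) belongs to."""

    POST_SURGERY = "post_surgery"
    CHEMOTHERAPY = "chemotherapy"


class Dimension(str, enum.Enum):
    """Rated dimension of a symptom."""

    OCCURRENCE = "occurrence"
    FREQUENCY = "frequency"
    DISTRESS = "distress"


class Severity(str, enum.Enum):
    """Two-tier alert severity: red demands contact within one hour,
    yellow the same working day."""

    RED = "red"
    YELLOW = "yellow"


class RulesetError(ValueError):
    """Raised for unparseable or internally inconsistent ruleset configs."""


@dataclass(frozen=True)
class RatingScale:
    """Ordered response labels with ascending integer severity codes.

    Occurrence is binary (codes 0/1); frequency and distress are 4-point
    ordinal scales coded 1..4.  Comparisons elsewhere are always by code,
    never by string inequality.
    """

    dimension: Dimension
    labels: tuple[str, ...]
    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.codes):
            raise RulesetError(
                f"scale for {self.dimension.value}: labels and codes differ in length"
            )
        if len(set(self.labels)) != len(self.labels):
            raise RulesetError(f"scale for {self.dimension.value}: duplicate labels")
        if any(b <= a for a, b in zip(self.codes, self.codes[1:])):
            raise RulesetError(
                f"scale for {self.dimension.value}: codes must be strictly increasing"
            )
        expected = 2 if self.dimension is Dimension.OCCURRENCE else 4
        if len(self.labels) != expected:
            raise RulesetError(
                f"scale for {self.dimension.value}: expected {expected} labels, "
                f"got {len(self.labels)}"
            )

    def code_for(self, label: str) -> int:
        try:
            return self.codes[self.labels.index(label)]
        except ValueError:
            raise RulesetError(
                f"label {label!r} not on the {self.dimension.value} scale"
            ) from None

    def label_for(self, code: int) -> str:
        try:
            return self.labels[self.codes.index(code)]
        except ValueError:
            raise RulesetError(
                f"code {code!r} not on the {self.dimension.value} scale"
            ) from None


@dataclass(frozen=True)
class SymptomDefinition:
    """One symptom in the catalog: which dimensions are asked, in which phases."""

    symptom_id: str
    display_name: str
    dimensions_assessed: frozenset[Dimension]
    phases: frozenset[Phase]

    def __post_init__(self) -> None:
        if Dimension.OCCURRENCE not in self.dimensions_assessed:
            raise RulesetError(
                f"symptom {self.symptom_id}: occurrence must always be assessed"
            )
        if not self.phases:
            raise RulesetError(f"symptom {self.symptom_id}: at least one phase required")


@dataclass(frozen=True)
class AlertRule:
    """A single alert-triggering rule.

    ``window_days`` is the number of calendar-consecutive qualifying days
    required before the alert fires (1 = a single report suffices).
    """

    rule_id: str
    symptom_id: str
    dimension: Dimension
    qualifying_responses: frozenset[str]
    window_days: int
    severity: Severity
    phase: Phase

    def __post_init__(self) -> None:
        if not self.qualifying_responses:
            raise RulesetError(f"rule {self.rule_id}: empty qualifying response set")
        if self.window_days < 1:
            raise RulesetError(f"rule {self.rule_id}: window_days must be >= 1")


@dataclass(frozen=True)
class Ruleset:
    """Validated bundle of symptom catalog, rating scales, and alert rules."""

    catalog: tuple[SymptomDefinition, ...]
    rules: tuple[AlertRule, ...]
    scales: dict[Dimension, RatingScale] = field(compare=True)

    def __post_init__(self) -> None:
        seen_symptoms: set[str] = set()
        for sym in self.catalog:
            if sym.symptom_id in seen_symptoms:
                raise RulesetError(f"duplicate symptom_id {sym.symptom_id!r}")
            seen_symptoms.add(sym.symptom_id)
        for dim in Dimension:
            if dim not in self.scales:
                raise RulesetError(f"missing rating scale for {dim.value}")
        by_id = {s.symptom_id: s for s in self.catalog}
        seen_rules: set[str] = set()
        for rule in self.rules:
            if rule.rule_id in seen_rules:
                raise RulesetError(f"duplicate rule_id {rule.rule_id!r}")
            seen_rules.add(rule.rule_id)
            sym = by_id.get(rule.symptom_id)
            if sym is None:
                raise RulesetError(
                    f"rule {rule.rule_id}: unknown symptom {rule.symptom_id!r}"
                )
            if rule.phase not in sym.phases:
                raise RulesetError(
                    f"rule {rule.rule_id}: symptom {rule.symptom_id!r} is not "
                    f"assessed in phase {rule.phase.value}"
                )
            if rule.dimension not in sym.dimensions_assessed:
                raise RulesetError(
                    f"rule {rule.rule_id}: dimension {rule.dimension.value} is not "
                    f"assessed for symptom {rule.symptom_id!r}"
                )
            scale = self.scales[rule.dimension]
            unknown = rule.qualifying_responses - set(scale.labels)
            if unknown:
                raise RulesetError(
                    f"rule {rule.rule_id}: label(s) {sorted(unknown)!r} not on the "
                    f"{rule.dimension.value} scale"
                )

    def symptom(self, symptom_id: str) -> SymptomDefinition:
        for sym in self.catalog:
            if sym.symptom_id == symptom_id:
                return sym
        raise KeyError(symptom_id)

    def rules_for_phase(self, phase: Phase) -> tuple[AlertRule, ...]:
        return tuple(r for r in self.rules if r.phase is phase)

    def symptoms_for_phase(self, phase: Phase) -> tuple[SymptomDefinition, ...]:
        return tuple(s for s in self.catalog if phase in s.phases)


def default_scales(
    frequency_labels: tuple[str, ...] = ("Seldom", "Sometimes", "Often", "Almost always"),
    distress_labels: tuple[str, ...] = ("A little", "Somewhat", "Rather much", "Very much"),
) -> dict[Dimension, RatingScale]:
    """Default occurrence/frequency/distress scales.

    The two lowest frequency and distress labels are configurable
    placeholders; only the alert-qualifying upper categories are fixed by
    the built-in ruleset.
    """
    return {
        Dimension.OCCURRENCE: RatingScale(Dimension.OCCURRENCE, ("No", "Yes"), (0, 1)),
        Dimension.FREQUENCY: RatingScale(Dimension.FREQUENCY, frequency_labels, (1, 2, 3, 4)),
        Dimension.DISTRESS: RatingScale(Dimension.DISTRESS, distress_labels, (1, 2, 3, 4)),
    }


def _coerce_label(value: object) -> str:
    # YAML 1.1 parses bare Yes/No as booleans; map them back to labels.
    if value is True:
        return "Yes"
    if value is False:
        return "No"
    return str(value)


def load_ruleset(config_text: str) -> Ruleset:
    """Parse and validate a YAML ruleset document.

    Raises :class:`RulesetError` with context for parse failures, dangling
    symptom references, and labels not on the named dimension's scale.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise RulesetError(f"ruleset config does not parse: {exc}") from exc
    if not isinstance(doc, dict):
        raise RulesetError("ruleset config must be a mapping")
    for key in ("scales", "symptoms", "rules"):
        if key not in doc:
            raise RulesetError(f"ruleset config missing top-level key {key!r}")

    scales: dict[Dimension, RatingScale] = {}
    for dim_name, spec in doc["scales"].items():
        try:
            dim = Dimension(dim_name)
        except ValueError:
            raise RulesetError(f"unknown dimension {dim_name!r} in scales") from None
        scales[dim] = RatingScale(
            dimension=dim,
            labels=tuple(_coerce_label(x) for x in spec["labels"]),
            codes=tuple(int(c) for c in spec["codes"]),
        )

    catalog = []
    for entry in doc["symptoms"]:
        try:
            catalog.append(
                SymptomDefinition(
                    symptom_id=str(entry["id"]),
                    display_name=str(entry.get("name", entry["id"])),
                    dimensions_assessed=frozenset(
                        Dimension(d) for d in entry["dimensions"]
                    ),
                    phases=frozenset(Phase(p) for p in entry["phases"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise RulesetError(f"bad symptom entry {entry!r}: {exc}") from exc

    rules = []
    for entry in doc["rules"]:
        try:
            rules.append(
                AlertRule(
                    rule_id=str(entry["id"]),
                    symptom_id=str(entry["symptom"]),
                    dimension=Dimension(entry["dimension"]),
                    qualifying_responses=frozenset(
                        _coerce_label(x) for x in entry["responses"]
                    ),
                    window_days=int(entry["window_days"]),
                    severity=Severity(entry["severity"]),
                    phase=Phase(entry["phase"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise RulesetError(f"bad rule entry {entry!r}: {exc}") from exc

    return Ruleset(catalog=tuple(catalog), rules=tuple(rules), scales=scales)


def serialize_ruleset(ruleset: Ruleset) -> str:
    """Render a ruleset back to YAML such that ``load_ruleset`` round-trips it."""
    scale_order = {s.dimension: s for s in ruleset.scales.values()}
    doc = {
        "scales": {
            dim.value: {
                "labels": list(scale_order[dim].labels),
                "codes": list(scale_order[dim].codes),
            }
            for dim in Dimension
        },
        "symptoms": [
            {
                "id": s.symptom_id,
                "name": s.display_name,
                "dimensions": sorted(d.value for d in s.dimensions_assessed),
                "phases": sorted(p.value for p in s.phases),
            }
            for s in ruleset.catalog
        ],
        "rules": [
            {
                "id": r.rule_id,
                "symptom": r.symptom_id,
                "dimension": r.dimension.value,
                "responses": sorted(r.qualifying_responses),
                "window_days": r.window_days,
                "severity": r.severity.value,
                "phase": r.phase.value,
            }
            for r in ruleset.rules
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


# Built-in ruleset for pancreatic-surgery follow-up.  12 symptoms are
# assessed after surgery and 3 more during adjuvant chemotherapy; the
# chemotherapy panel uses single-report windows only because patients in
# that phase already have weekly nurse contact.
_BUILTIN_PANCREAS_YAML = """\
scales:
  occurrence: {labels: ["No", "Yes"], codes: [0, 1]}
  frequency: {labels: [Seldom, Sometimes, Often, Almost always], codes: [1, 2, 3, 4]}
  distress: {labels: [A little, Somewhat, Rather much, Very much], codes: [1, 2, 3, 4]}
symptoms:
  - {id: fever, name: Fever,
     dimensions: [occurrence], phases: [post_surgery, chemotherapy]}
  - {id: pain, name: Pain,
     dimensions: [occurrence, frequency, distress], phases: [post_surgery, chemotherapy]}
  - {id: vomiting, name: Vomiting,
     dimensions: [occurrence, frequency, distress], phases: [post_surgery, chemotherapy]}
  - {id: dizziness, name: Dizziness,
     dimensions: [occurrence, frequency, distress], phases: [post_surgery, chemotherapy]}
  - {id: loose_stool, name: Loose stool,
     dimensions: [occurrence, frequency, distress], phases: [post_surgery, chemotherapy]}
  - {id: constipation, name: Constipation,
     dimensions: [occurrence, distress], phases: [post_surgery, chemotherapy]}
  - {id: eating_difficulties, name: Eating difficulties,
     dimensions: [occurrence, frequency, distress], phases: [post_surgery, chemotherapy]}
  - {id: nausea, name: Nausea,
     dimensions: [occurrence, frequency, distress], phases: [post_surgery, chemotherapy]}
  - {id: fatigue, name: Fatigue,
     dimensions: [occurrence, frequency, distress], phases: [post_surgery, chemotherapy]}
  - {id: sadness_depression_worry, name: Sadness/depression/worry,
     dimensions: [occurrence, frequency, distress], phases: [post_surgery, chemotherapy]}
  - {id: activities_home, name: Problems performing activities at home,
     dimensions: [occurrence, distress], phases: [post_surgery, chemotherapy]}
  - {id: activities_outside, name: Problems performing activities outside home,
     dimensions: [occurrence, distress, frequency], phases: [post_surgery, chemotherapy]}
  - {id: breathing_difficulties, name: Breathing difficulties,
     dimensions: [occurrence, frequency, distress], phases: [chemotherapy]}
  - {id: numbness_tingling, name: Numbness/tingling in hands and/or feet,
     dimensions: [occurrence, frequency, distress], phases: [chemotherapy]}
  - {id: svp_picc, name: Swelling/pain/redness from SVP/PICC,
     dimensions: [occurrence], phases: [chemotherapy]}
rules:
  # --- after surgery ---
  - {id: ps_fever_red, symptom: fever, dimension: occurrence,
     responses: ["Yes"], window_days: 1, severity: red, phase: post_surgery}
  - {id: ps_pain_red, symptom: pain, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: red, phase: post_surgery}
  - {id: ps_vomiting_red, symptom: vomiting, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: red, phase: post_surgery}
  - {id: ps_dizziness_red, symptom: dizziness, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: red, phase: post_surgery}
  - {id: ps_vomiting_yellow, symptom: vomiting, dimension: frequency,
     responses: [Sometimes, Often, Almost always], window_days: 2, severity: yellow,
     phase: post_surgery}
  - {id: ps_dizziness_yellow, symptom: dizziness, dimension: frequency,
     responses: [Sometimes, Often, Almost always], window_days: 2, severity: yellow,
     phase: post_surgery}
  - {id: ps_loose_stool_yellow, symptom: loose_stool, dimension: frequency,
     responses: [Often, Almost always], window_days: 3, severity: yellow,
     phase: post_surgery}
  - {id: ps_constipation_yellow, symptom: constipation, dimension: occurrence,
     responses: ["Yes"], window_days: 3, severity: yellow, phase: post_surgery}
  - {id: ps_eating_difficulties_yellow, symptom: eating_difficulties,
     dimension: frequency, responses: [Often, Almost always], window_days: 7,
     severity: yellow, phase: post_surgery}
  - {id: ps_pain_yellow, symptom: pain, dimension: frequency,
     responses: [Often, Almost always], window_days: 7, severity: yellow,
     phase: post_surgery}
  - {id: ps_nausea_yellow, symptom: nausea, dimension: frequency,
     responses: [Often, Almost always], window_days: 7, severity: yellow,
     phase: post_surgery}
  - {id: ps_fatigue_yellow, symptom: fatigue, dimension: distress,
     responses: [Rather much, Very much], window_days: 7, severity: yellow,
     phase: post_surgery}
  - {id: ps_sadness_yellow, symptom: sadness_depression_worry, dimension: distress,
     responses: [Rather much, Very much], window_days: 7, severity: yellow,
     phase: post_surgery}
  - {id: ps_activities_home_yellow, symptom: activities_home, dimension: distress,
     responses: [Rather much, Very much], window_days: 7, severity: yellow,
     phase: post_surgery}
  - {id: ps_activities_outside_yellow, symptom: activities_outside, dimension: distress,
     responses: [Rather much, Very much], window_days: 7, severity: yellow,
     phase: post_surgery}
  # --- during chemotherapy (single-report windows only) ---
  - {id: ct_fever_red, symptom: fever, dimension: occurrence,
     responses: ["Yes"], window_days: 1, severity: red, phase: chemotherapy}
  - {id: ct_breathing_red, symptom: breathing_difficulties, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: red, phase: chemotherapy}
  - {id: ct_nausea_red, symptom: nausea, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: red, phase: chemotherapy}
  - {id: ct_vomiting_red, symptom: vomiting, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: red, phase: chemotherapy}
  - {id: ct_numbness_red, symptom: numbness_tingling, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: red, phase: chemotherapy}
  - {id: ct_eating_difficulties_red, symptom: eating_difficulties, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: red, phase: chemotherapy}
  - {id: ct_svp_picc_yellow, symptom: svp_picc, dimension: occurrence,
     responses: ["Yes"], window_days: 1, severity: yellow, phase: chemotherapy}
  - {id: ct_loose_stool_yellow, symptom: loose_stool, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: yellow, phase: chemotherapy}
  - {id: ct_pain_yellow, symptom: pain, dimension: frequency,
     responses: [Almost always], window_days: 1, severity: yellow, phase: chemotherapy}
  - {id: ct_dizziness_yellow, symptom: dizziness, dimension: frequency,
     responses: [Often, Almost always], window_days: 1, severity: yellow,
     phase: chemotherapy}
  - {id: ct_vomiting_yellow, symptom: vomiting, dimension: frequency,
     responses: [Often], window_days: 1, severity: yellow, phase: chemotherapy}
  - {id: ct_nausea_yellow, symptom: nausea, dimension: frequency,
     responses: [Often], window_days: 1, severity: yellow, phase: chemotherapy}
  - {id: ct_breathing_yellow, symptom: breathing_difficulties, dimension: frequency,
     responses: [Often], window_days: 1, severity: yellow, phase: chemotherapy}
  - {id: ct_constipation_yellow, symptom: constipation, dimension: distress,
     responses: [Very much], window_days: 1, severity: yellow, phase: chemotherapy}
  - {id: ct_sadness_yellow, symptom: sadness_depression_worry, dimension: distress,
     responses: [Very much], window_days: 1, severity: yellow, phase: chemotherapy}
"""


def builtin_pancreas_ruleset() -> Ruleset:
    """The built-in pancreatic-surgery ruleset (both care phases)."""
    return load_ruleset(_BUILTIN_PANCREAS_YAML)
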