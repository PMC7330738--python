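"""Ruleset definition, validation, built-in catalog, and round-tripping."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sentinel.rules import (
    AlertRule,
    Dimension,
    Phase,
    RatingScale,
    Ruleset,
    RulesetError,
    Severity,
    SymptomDefinition,
    default_scales,
    load_ruleset,
    serialize_ruleset,
)


class TestRatingScale:
    def test_occurrence_scale_is_binary(self):
        scale = default_scales()[Dimension.OCCURRENCE]
        assert scale.labels == ("No", "Yes")
        assert scale.codes == (0, 1)

    def test_four_point_scales(self):
        scales = default_scales()
        assert len(scales[Dimension.FREQUENCY].labels) == 4
        assert scales[Dimension.DISTRESS].codes == (1, 2, 3, 4)

    def test_label_code_lookup(self):
        scale = default_scales()[Dimension.FREQUENCY]
        assert scale.code_for("Often") == 3
        assert scale.label_for(4) == "Almost always"

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(RulesetError):
            RatingScale(Dimension.FREQUENCY, ("a", "b", "c", "d"), (1, 2, 3))

    def test_non_increasing_codes_rejected(self):
        with pytest.raises(RulesetError):
            RatingScale(Dimension.OCCURRENCE, ("No", "Yes"), (1, 1))

    def test_occurrence_must_have_two_labels(self):
        with pytest.raises(RulesetError):
            RatingScale(Dimension.OCCURRENCE, ("No", "Maybe", "Yes"), (0, 1, 2))

    def test_custom_lower_labels_allowed(self):
        scales = default_scales(frequency_labels=("Sällan", "Ibland", "Often", "Almost always"))
        assert scales[Dimension.FREQUENCY].code_for("Ibland") == 2


class TestBuiltinRuleset:
    """Table-driven fidelity checks of the built-in pancreas ruleset."""

    def test_rule_counts_per_phase(self, ruleset):
        ps = ruleset.rules_for_phase(Phase.POST_SURGERY)
        ct = ruleset.rules_for_phase(Phase.CHEMOTHERAPY)
        assert len(ps) == 15
        assert len(ct) == 15
        assert len(ruleset.rules) == 30

    def test_severity_counts(self, ruleset):
        ps = ruleset.rules_for_phase(Phase.POST_SURGERY)
        ct = ruleset.rules_for_phase(Phase.CHEMOTHERAPY)
        assert sum(r.severity is Severity.RED for r in ps) == 4
        assert sum(r.severity is Severity.YELLOW for r in ps) == 11
        assert sum(r.severity is Severity.RED for r in ct) == 6
        assert sum(r.severity is Severity.YELLOW for r in ct) == 9

    def test_symptom_counts_per_phase(self, ruleset):
        ps_syms = ruleset.symptoms_for_phase(Phase.POST_SURGERY)
        ct_syms = ruleset.symptoms_for_phase(Phase.CHEMOTHERAPY)
        assert len(ps_syms) == 12
        assert len(ct_syms) == 15
        shared = {s.symptom_id for s in ps_syms} & {s.symptom_id for s in ct_syms}
        assert len(shared) == 12

    def test_post_surgery_red_rules(self, ruleset):
        reds = {
            (r.symptom_id, r.dimension, frozenset(r.qualifying_responses), r.window_days)
            for r in ruleset.rules_for_phase(Phase.POST_SURGERY)
            if r.severity is Severity.RED
        }
        assert reds == {
            ("fever", Dimension.OCCURRENCE, frozenset({"Yes"}), 1),
            ("pain", Dimension.FREQUENCY, frozenset({"Almost always"}), 1),
            ("vomiting", Dimension.FREQUENCY, frozenset({"Almost always"}), 1),
            ("dizziness", Dimension.FREQUENCY, frozenset({"Almost always"}), 1),
        }

    @pytest.mark.parametrize(
        "symptom, dimension, responses, window, severity",
        [
            ("vomiting", Dimension.FREQUENCY, {"Sometimes", "Often", "Almost always"}, 2, Severity.YELLOW),
            ("dizziness", Dimension.FREQUENCY, {"Sometimes", "Often", "Almost always"}, 2, Severity.YELLOW),
            ("loose_stool", Dimension.FREQUENCY, {"Often", "Almost always"}, 3, Severity.YELLOW),
            ("constipation", Dimension.OCCURRENCE, {"Yes"}, 3, Severity.YELLOW),
            ("eating_difficulties", Dimension.FREQUENCY, {"Often", "Almost always"}, 7, Severity.YELLOW),
            ("pain", Dimension.FREQUENCY, {"Often", "Almost always"}, 7, Severity.YELLOW),
            ("nausea", Dimension.FREQUENCY, {"Often", "Almost always"}, 7, Severity.YELLOW),
            ("fatigue", Dimension.DISTRESS, {"Rather much", "Very much"}, 7, Severity.YELLOW),
            ("sadness_depression_worry", Dimension.DISTRESS, {"Rather much", "Very much"}, 7, Severity.YELLOW),
            ("activities_home", Dimension.DISTRESS, {"Rather much", "Very much"}, 7, Severity.YELLOW),
            ("activities_outside", Dimension.DISTRESS, {"Rather much", "Very much"}, 7, Severity.YELLOW),
        ],
    )
    def test_post_surgery_yellow_rules(self, ruleset, symptom, dimension, responses, window, severity):
        matches = [
            r
            for r in ruleset.rules_for_phase(Phase.POST_SURGERY)
            if r.symptom_id == symptom
            and r.dimension is dimension
            and r.severity is severity
        ]
        assert len(matches) == 1
        rule = matches[0]
        assert set(rule.qualifying_responses) == responses
        assert rule.window_days == window

    @pytest.mark.parametrize(
        "symptom, dimension, responses, severity",
        [
            ("fever", Dimension.OCCURRENCE, {"Yes"}, Severity.RED),
            ("breathing_difficulties", Dimension.FREQUENCY, {"Almost always"}, Severity.RED),
            ("nausea", Dimension.FREQUENCY, {"Almost always"}, Severity.RED),
            ("vomiting", Dimension.FREQUENCY, {"Almost always"}, Severity.RED),
            ("numbness_tingling", Dimension.FREQUENCY, {"Almost always"}, Severity.RED),
            ("eating_difficulties", Dimension.FREQUENCY, {"Almost always"}, Severity.RED),
            ("svp_picc", Dimension.OCCURRENCE, {"Yes"}, Severity.YELLOW),
            ("loose_stool", Dimension.FREQUENCY, {"Almost always"}, Severity.YELLOW),
            ("pain", Dimension.FREQUENCY, {"Almost always"}, Severity.YELLOW),
            ("dizziness", Dimension.FREQUENCY, {"Often", "Almost always"}, Severity.YELLOW),
            ("vomiting", Dimension.FREQUENCY, {"Often"}, Severity.YELLOW),
            ("nausea", Dimension.FREQUENCY, {"Often"}, Severity.YELLOW),
            ("breathing_difficulties", Dimension.FREQUENCY, {"Often"}, Severity.YELLOW),
            ("constipation", Dimension.DISTRESS, {"Very much"}, Severity.YELLOW),
            ("sadness_depression_worry", Dimension.DISTRESS, {"Very much"}, Severity.YELLOW),
        ],
    )
    def test_chemotherapy_rules(self, ruleset, symptom, dimension, responses, severity):
        matches = [
            r
            for r in ruleset.rules_for_phase(Phase.CHEMOTHERAPY)
            if r.symptom_id == symptom
            and r.dimension is dimension
            and r.severity is severity
            and set(r.qualifying_responses) == responses
        ]
        assert len(matches) == 1

    def test_chemotherapy_rules_single_report_windows(self, ruleset):
        assert all(
            r.window_days == 1 for r in ruleset.rules_for_phase(Phase.CHEMOTHERAPY)
        )

    def test_post_surgery_window_lengths(self, ruleset):
        windows = {r.window_days for r in ruleset.rules_for_phase(Phase.POST_SURGERY)}
        assert windows == {1, 2, 3, 7}

    def test_qualifying_sets_are_contiguous_and_jointly_upsets(self, ruleset):
        # Each built-in rule names a contiguous band of its scale, and the
        # rules for one (phase, symptom, dimension) jointly cover a top
        # segment (an "Often"-only yellow rule pairs with an
        # "Almost always" red rule).
        unions: dict[tuple, set[int]] = {}
        for rule in ruleset.rules:
            scale = ruleset.scales[rule.dimension]
            codes = sorted(scale.code_for(label) for label in rule.qualifying_responses)
            assert codes == list(range(codes[0], codes[-1] + 1)), rule.rule_id
            key = (rule.phase, rule.symptom_id, rule.dimension)
            unions.setdefault(key, set()).update(codes)
        for key, codes in unions.items():
            scale = ruleset.scales[key[2]]
            top = set(scale.codes[-len(codes):])
            assert codes == top, key

    def test_chemo_only_symptoms(self, ruleset):
        chemo_only = {
            s.symptom_id for s in ruleset.catalog if s.phases == frozenset({Phase.CHEMOTHERAPY})
        }
        assert chemo_only == {"breathing_difficulties", "numbness_tingling", "svp_picc"}

    def test_occurrence_always_assessed(self, ruleset):
        assert all(Dimension.OCCURRENCE in s.dimensions_assessed for s in ruleset.catalog)


class TestLoadValidation:
    def test_unknown_label_rejected(self):
        text = (
            "scales:\n"
            "  occurrence: {labels: ['No', 'Yes'], codes: [0, 1]}\n"
            "  frequency: {labels: [Seldom, Sometimes, Often, Almost always], codes: [1, 2, 3, 4]}\n"
            "  distress: {labels: [A little, Somewhat, Rather much, Very much], codes: [1, 2, 3, 4]}\n"
            "symptoms:\n"
            "  - {id: pain, name: Pain, dimensions: [occurrence, frequency], phases: [post_surgery]}\n"
            "rules:\n"
            "  - {id: r1, symptom: pain, dimension: frequency, responses: [Always],\n"
            "     window_days: 1, severity: red, phase: post_surgery}\n"
        )
        with pytest.raises(RulesetError, match="r1.*Always"):
            load_ruleset(text)

    def test_dangling_symptom_rejected(self, ruleset):
        text = serialize_ruleset(ruleset).replace("symptom: fever", "symptom: chills", 1)
        with pytest.raises(RulesetError, match="chills"):
            load_ruleset(text)

    def test_parse_failure_reported(self):
        with pytest.raises(RulesetError, match="parse"):
            load_ruleset("scales: [unbalanced")

    def test_missing_top_level_key(self):
        with pytest.raises(RulesetError, match="rules"):
            load_ruleset("scales: {}\nsymptoms: []\n")

    def test_empty_rules_valid(self, ruleset):
        empty = Ruleset(catalog=ruleset.catalog, rules=(), scales=ruleset.scales)
        assert empty.rules == ()
        assert load_ruleset(serialize_ruleset(empty)) == empty

    def test_duplicate_rule_id_rejected(self, ruleset):
        with pytest.raises(RulesetError, match="duplicate"):
            Ruleset(
                catalog=ruleset.catalog,
                rules=(ruleset.rules[0], ruleset.rules[0]),
                scales=ruleset.scales,
            )

    def test_rule_phase_must_match_symptom(self, ruleset):
        bad = AlertRule(
            rule_id="x",
            symptom_id="svp_picc",  # chemo-only symptom
            dimension=Dimension.OCCURRENCE,
            qualifying_responses=frozenset({"Yes"}),
            window_days=1,
            severity=Severity.RED,
            phase=Phase.POST_SURGERY,
        )
        with pytest.raises(RulesetError, match="phase"):
            Ruleset(catalog=ruleset.catalog, rules=(bad,), scales=ruleset.scales)

    def test_rule_dimension_must_be_assessed(self, ruleset):
        bad = AlertRule(
            rule_id="x",
            symptom_id="fever",  # occurrence-only symptom
            dimension=Dimension.FREQUENCY,
            qualifying_responses=frozenset({"Often"}),
            window_days=1,
            severity=Severity.RED,
            phase=Phase.POST_SURGERY,
        )
        with pytest.raises(RulesetError, match="dimension"):
            Ruleset(catalog=ruleset.catalog, rules=(bad,), scales=ruleset.scales)


class TestRoundTrip:
    def test_builtin_round_trips(self, ruleset):
        assert load_ruleset(serialize_ruleset(ruleset)) == ruleset

    def test_modified_copy_round_trips_and_differs(self, ruleset):
        trimmed = Ruleset(
            catalog=ruleset.catalog, rules=ruleset.rules[:-1], scales=ruleset.scales
        )
        again = load_ruleset(serialize_ruleset(trimmed))
        assert again == trimmed
        assert again != ruleset

    def test_yes_label_survives_yaml(self, ruleset):
        # "Yes" is a YAML 1.1 boolean; round-trip must preserve it as a label.
        reloaded = load_ruleset(serialize_ruleset(ruleset))
        fever = next(r for r in reloaded.rules if r.rule_id == "ps_fever_red")
        assert fever.qualifying_responses == frozenset({"Yes"})


# --- property: serialize∘load is identity on random rulesets ---------------

_label = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), max_codepoint=0x2FF),
    min_size=1,
    max_size=12,
)


@st.composite
def rulesets(draw) -> Ruleset:
    freq_labels = tuple(draw(st.lists(_label, min_size=4, max_size=4, unique=True)))
    dist_labels = tuple(draw(st.lists(_label, min_size=4, max_size=4, unique=True)))
    scales = default_scales(frequency_labels=freq_labels, distress_labels=dist_labels)
    n_symptoms = draw(st.integers(1, 6))
    catalog = []
    for i in range(n_symptoms):
        extra = draw(
            st.sets(st.sampled_from([Dimension.FREQUENCY, Dimension.DISTRESS]), max_size=2)
        )
        phases = draw(
            st.sets(st.sampled_from(list(Phase)), min_size=1, max_size=2)
        )
        catalog.append(
            SymptomDefinition(
                symptom_id=f"s{i}",
                display_name=draw(_label),
                dimensions_assessed=frozenset({Dimension.OCCURRENCE} | extra),
                phases=frozenset(phases),
            )
        )
    rules = []
    n_rules = draw(st.integers(0, 8))
    for j in range(n_rules):
        sym = draw(st.sampled_from(catalog))
        dim = draw(st.sampled_from(sorted(sym.dimensions_assessed, key=lambda d: d.value)))
        scale = scales[dim]
        responses = draw(
            st.sets(st.sampled_from(scale.labels), min_size=1, max_size=len(scale.labels))
        )
        phase = draw(st.sampled_from(sorted(sym.phases, key=lambda p: p.value)))
        rules.append(
            AlertRule(
                rule_id=f"r{j}",
                symptom_id=sym.symptom_id,
                dimension=dim,
                qualifying_responses=frozenset(responses),
                window_days=draw(st.sampled_from([1, 2, 3, 7])),
                severity=draw(st.sampled_from(list(Severity))),
                phase=phase,
            )
        )
    return Ruleset(catalog=tuple(catalog), rules=tuple(rules), scales=scales)


@settings(max_examples=60, deadline=None)
@given(rulesets())
def test_serialize_load_identity(rs: Ruleset):
    assert load_ruleset(serialize_ruleset(rs)) == rs
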