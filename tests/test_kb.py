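"""Knowledge-pack loading, validation, serialization, Kleene logic, linting."""
import random

import pytest

from ltxcdss import builtin_referral_pack, lint_pack, load_pack, serialize_pack
from ltxcdss.errors import PackValidationError
from ltxcdss.kb import Comparator, Condition, ConditionKind, all_of, any_of, atom, not_
from ltxcdss.patient import UNKNOWN

MINIMAL = """
name: mini
version: "1"
facts: {a: boolean, b: boolean}
rules:
  - id: r1
    level: 1
    category: referral_criteria
    if: {fact: a, op: eq, value: true}
    then: [{assert: {b: true}}]
"""


class TestLoadPack:
    def test_minimal_pack_loads(self):
        pack = load_pack(MINIMAL)
        assert pack.name == "mini" and len(pack.rules) == 1

    def test_bundled_pack_has_referral_rule_set(self, referral_pack):
        assert referral_pack.name == "imamltx-referral"
        assert len(referral_pack.rules) >= 13
        assert len(referral_pack.rules_in_category("referral_criteria")) >= 10

    def test_empty_rule_list_is_valid(self):
        pack = load_pack('name: empty\nversion: "1"\nfacts: {}\nrules: []\n')
        assert pack.rules == []

    def test_undeclared_fact_named_in_error(self):
        bad = MINIMAL.replace("{fact: a, op: eq, value: true}", "{fact: xyz, op: eq, value: true}")
        with pytest.raises(PackValidationError, match="xyz"):
            load_pack(bad)

    def test_all_violations_reported_not_just_first(self):
        bad = """
name: bad
version: "1"
facts: {a: boolean}
rules:
  - id: r1
    if: {fact: missing1, op: eq, value: true}
    then: [{assert: {missing2: true}}]
  - id: r1
    if: {fact: a, op: eq, value: true}
    then: [{assert: {a: true}}]
"""
        with pytest.raises(PackValidationError) as exc:
            load_pack(bad)
        text = str(exc.value)
        assert "missing1" in text and "missing2" in text and "duplicate" in text

    def test_malformed_condition_rejected(self):
        bad = MINIMAL.replace("{fact: a, op: eq, value: true}", "{op: eq, value: true}")
        with pytest.raises(PackValidationError, match="condition"):
            load_pack(bad)


class TestSerializationRoundTrip:
    def test_bundled_pack_round_trips(self, referral_pack):
        assert load_pack(serialize_pack(referral_pack)) == referral_pack

    def test_random_packs_round_trip(self):
        rng = random.Random(7)
        for _ in range(20):
            pack = _random_pack(rng)
            assert load_pack(serialize_pack(pack)) == pack


def _random_condition(rng, facts, depth=0):
    if depth >= 3 or rng.random() < 0.4:
        return atom(rng.choice(facts), "eq", rng.choice([True, False]))
    kind = rng.choice(["all", "any", "not"])
    if kind == "not":
        return not_(_random_condition(rng, facts, depth + 1))
    kids = [_random_condition(rng, facts, depth + 1) for _ in range(rng.randint(1, 3))]
    return all_of(*kids) if kind == "all" else any_of(*kids)


def _random_pack(rng):
    facts = [f"f{i}" for i in range(6)]
    doc_facts = "\n".join(f"  {f}: boolean" for f in facts)
    rules = []
    for i in range(rng.randint(1, 5)):
        cond = _random_condition(rng, facts)
        rules.append((f"r{i}", cond, rng.choice(facts)))
    from ltxcdss.kb import KnowledgePack, Rule, RuleAction
    return KnowledgePack(
        name="rand", version="1",
        facts={f: "boolean" for f in facts},
        rules=[
            Rule(rid, level=rng.randint(1, 4), category="referral_criteria",
                 antecedent=cond, then_actions=(RuleAction.assert_(target, True),))
            for rid, cond, target in rules
        ],
    )


# --- three-valued logic vs an independent numeric Kleene oracle -----------

def _kleene_oracle(cond, assignment):
    """Strong Kleene logic with F=0, U=0.5, T=1: and=min, or=max, not=1-x."""
    if cond.kind is ConditionKind.atom:
        v = assignment.get(cond.fact)
        if v is None:
            return 0.5
        truth = (v == cond.operand) if cond.comparator is Comparator.eq else (v != cond.operand)
        return 1.0 if truth else 0.0
    if cond.kind is ConditionKind.not_:
        return 1.0 - _kleene_oracle(cond.children[0], assignment)
    vals = [_kleene_oracle(c, assignment) for c in cond.children]
    return min(vals) if cond.kind is ConditionKind.and_ else max(vals)


def _as_number(value):
    if value is UNKNOWN:
        return 0.5
    return 1.0 if value else 0.0


def _enumerate_assignments(facts):
    import itertools
    for combo in itertools.product([True, False, None], repeat=len(facts)):
        yield {f: v for f, v in zip(facts, combo) if v is not None}


class TestThreeValuedEvaluation:
    def test_matches_kleene_oracle_exhaustively(self):
        """Every {true,false,unknown}^k assignment, random conditions, k<=4."""
        rng = random.Random(11)
        facts = ["f0", "f1", "f2", "f3"]
        for _ in range(150):
            cond = _random_condition(rng, facts)
            for assignment in _enumerate_assignments(facts):
                expected = _kleene_oracle(cond, assignment)
                assert _as_number(cond.evaluate(assignment)) == expected

    @pytest.mark.parametrize(
        "cond,facts,expected",
        [
            (all_of(atom("a", "eq", True), atom("b", "eq", True)), {"b": False}, False),
            (all_of(atom("a", "eq", True), atom("b", "eq", True)), {"b": True}, UNKNOWN),
            (any_of(atom("a", "eq", True), atom("b", "eq", True)), {"b": True}, True),
            (not_(atom("a", "eq", True)), {}, UNKNOWN),
        ],
    )
    def test_unknown_propagation_rules(self, cond, facts, expected):
        assert cond.evaluate(facts) is expected

    def test_comparators(self):
        assert atom("x", "gt", 35).evaluate({"x": 36}) is True
        assert atom("x", "le", 65).evaluate({"x": 70}) is False
        assert atom("c", "in", ("III", "IV")).evaluate({"c": "III"}) is True
        assert atom("c", "ne", "A").evaluate({"c": "B"}) is True

    def test_ordering_comparator_on_non_number_raises(self):
        with pytest.raises(TypeError, match="non-numeric"):
            atom("x", "gt", 35).evaluate({"x": "high"})


class TestBundledReferralRules:
    def test_age_band(self, referral_pack):
        rule = referral_pack.get_rule("referral.age")
        assert rule.antecedent.evaluate({"age": 40}) is True
        assert rule.antecedent.evaluate({"age": 70}) is False
        assert rule.antecedent.evaluate({"age": 13}) is False
        assert rule.antecedent.evaluate({"age": 14}) is True
        assert rule.antecedent.evaluate({"age": 65}) is True

    def test_age_band_configurable(self):
        pack = builtin_referral_pack(age_min=18, age_max=60)
        rule = pack.get_rule("referral.age")
        assert rule.antecedent.evaluate({"age": 16}) is False
        assert rule.antecedent.evaluate({"age": 60}) is True

    def test_fev1_rule_encoded_as_published_but_parameterized(self, referral_pack):
        rule = referral_pack.get_rule("referral.copd.fev1")
        assert rule.antecedent.evaluate({"fev1_pct": 36}) is True
        assert rule.antecedent.evaluate({"fev1_pct": 35}) is False
        flipped = builtin_referral_pack(fev1_comparator="lt")
        assert flipped.get_rule("referral.copd.fev1").antecedent.evaluate({"fev1_pct": 20}) is True

    def test_nyha_rules_mutually_exclusive(self, referral_pack):
        """No symptom state can ever assign two NYHA classes."""
        nyha_rules = [r for r in referral_pack.rules if r.rule_id.startswith("referral.nyha.")]
        assert len(nyha_rules) == 4
        for symptoms in ["none", "normal-activity", "daily-activity-only", "at-rest"]:
            matches = [r for r in nyha_rules if r.antecedent.evaluate({"nyha_symptoms": symptoms}) is True]
            assert len(matches) == 1


class TestLint:
    def test_clean_bundled_pack(self, referral_pack):
        assert lint_pack(referral_pack).findings == []

    def test_self_dependent_rule_flagged(self):
        pack = load_pack("""
name: selfdep
version: "1"
facts: {a: boolean}
rules:
  - id: r1
    if: {fact: a, op: eq, value: true}
    then: [{assert: {a: true}}]
""")
        assert "self-dependent" in lint_pack(pack).kinds

    def test_contradictory_pair_flagged(self):
        pack = load_pack("""
name: contra
version: "1"
facts: {a: boolean, b: boolean, out: boolean}
rules:
  - id: r1
    if: {fact: a, op: eq, value: true}
    then: [{assert: {out: true}}]
  - id: r2
    if: {fact: b, op: eq, value: true}
    then: [{assert: {out: false}}]
""")
        assert "potential-contradiction" in lint_pack(pack).kinds

    def test_exclusive_antecedents_not_flagged(self):
        pack = load_pack("""
name: excl
version: "1"
facts: {mode: string, out: boolean}
rules:
  - id: r1
    if: {fact: mode, op: eq, value: x}
    then: [{assert: {out: true}}]
  - id: r2
    if: {fact: mode, op: eq, value: y}
    then: [{assert: {out: false}}]
""")
        assert "potential-contradiction" not in lint_pack(pack).kinds

    def test_empty_rule_flagged(self):
        pack = load_pack("""
name: hollow
version: "1"
facts: {a: boolean}
rules:
  - id: r1
    if: {fact: a, op: eq, value: true}
    then: []
""")
        assert "empty-rule" in lint_pack(pack).kinds
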