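"""Forward-chaining engine: worked example, traces, conflicts, oracle equivalence."""
import random

import pytest

from ltxcdss import explain, infer
from ltxcdss.errors import InferenceConflictError
from ltxcdss.kb import (
    KnowledgePack,
    Rule,
    RuleAction,
    all_of,
    atom,
    load_pack,
)
from ltxcdss.patient import UNKNOWN

REFERRAL = "referral_criteria_met"


class TestWorkedExample:
    def test_copd_chain_concludes_referral(self, referral_pack, copd_facts):
        res = infer(copd_facts, referral_pack)
        assert res.derived_facts["nyha_class"] == "III"
        assert REFERRAL in res.final_conclusions
        assert any("criteria of referral" in m.text for m in res.recommendations)

    @pytest.mark.parametrize(
        "flip",
        [
            {"fev1_pct": 30.0},
            {"dyspnea_history": False},
            {"recurrent_hospitalization": False},
            {"nyha_symptoms": "normal-activity"},
        ],
    )
    def test_flipping_any_criterion_removes_conclusion(self, referral_pack, copd_facts, flip):
        facts = {**copd_facts, **flip}
        res = infer(facts, referral_pack)
        assert REFERRAL not in res.final_conclusions
        assert res.derived_facts[REFERRAL] is False
        assert any("does not meet" in m.text for m in res.alerts)

    def test_empty_facts_defers_everything(self, referral_pack):
        res = infer({}, referral_pack)
        assert res.fired_rules == []
        assert res.final_conclusions == []
        assert "age" in res.data_requests and "esld" in res.data_requests

    def test_unknown_blocks_rather_than_fails(self, referral_pack, copd_facts):
        del copd_facts["nyha_symptoms"]
        res = infer(copd_facts, referral_pack)
        assert REFERRAL not in res.final_conclusions
        assert res.fact_value(REFERRAL) is UNKNOWN
        assert "nyha_symptoms" in res.data_requests


class TestExplanation:
    def test_copd_tree_structure(self, referral_pack, copd_facts):
        res = infer(copd_facts, referral_pack)
        tree = explain(res, REFERRAL)
        assert tree.rule_id == "referral.copd.criteria"
        assert len(tree.children) == 4
        by_fact = {c.fact: c for c in tree.children}
        # NYHA branch expands through the flag rule down to the class-III rule
        nyha = by_fact["nyha_class_3_or_4"]
        assert nyha.rule_id == "referral.copd.nyha_flag"
        assert nyha.children[0].rule_id == "referral.nyha.class3"
        assert nyha.children[0].children[0].fact == "nyha_symptoms"
        assert nyha.children[0].children[0].rule_id is None  # input leaf
        # every leaf is an input fact
        def leaves(node):
            return [node] if not node.children else [l for c in node.children for l in leaves(c)]
        assert all(l.rule_id is None for l in leaves(tree))

    def test_single_rule_gives_depth_one_tree(self):
        pack = load_pack("""
name: one
version: "1"
facts: {a: boolean, out: boolean}
conclusions: [out]
rules:
  - id: r1
    if: {fact: a, op: eq, value: true}
    then: [{assert: {out: true}}]
""")
        res = infer({"a": True}, pack)
        tree = explain(res, "out")
        assert tree.rule_id == "r1"
        assert [c.fact for c in tree.children] == ["a"]
        assert tree.children[0].rule_id is None

    def test_unknown_conclusion_raises(self, referral_pack, copd_facts):
        res = infer(copd_facts, referral_pack)
        with pytest.raises(KeyError, match="nonexistent"):
            explain(res, "nonexistent")


class TestConflicts:
    CONFLICT_PACK = """
name: clash
version: "1"
facts: {a: boolean, b: boolean, out: boolean}
rules:
  - id: yes_rule
    if: {fact: a, op: eq, value: true}
    then: [{assert: {out: true}}]
  - id: no_rule
    if: {fact: b, op: eq, value: true}
    then: [{assert: {out: false}}]
"""

    def test_conflicting_rules_raise_naming_both(self):
        pack = load_pack(self.CONFLICT_PACK)
        with pytest.raises(InferenceConflictError) as exc:
            infer({"a": True, "b": True}, pack)
        assert "yes_rule" in str(exc.value) and "no_rule" in str(exc.value)

    def test_derived_fact_never_overwrites_input(self):
        pack = load_pack(self.CONFLICT_PACK)
        with pytest.raises(InferenceConflictError, match="input"):
            infer({"a": True, "out": False}, pack)

    def test_idempotent_reassertion_is_fine(self):
        pack = load_pack(self.CONFLICT_PACK.replace("value: false}}]", "value: true}}]")
                         .replace("{assert: {out: false}}", "{assert: {out: true}}"))
        res = infer({"a": True, "b": True}, pack)
        assert res.derived_facts["out"] is True


# --- brute-force closure oracle -------------------------------------------

def _oracle_closure(pack, inputs):
    """Repeated full scanning with an independent literal-conjunction evaluator.

    Rules here are conjunctions of boolean literals; then/else assert facts
    True.  Returns the final fact map.
    """
    facts = dict(inputs)
    applied = set()
    changed = True
    while changed:
        changed = False
        for rule in pack.rules:
            if rule.rule_id in applied:
                continue
            # evaluate conjunction of eq-literals three-valuedly
            value = True
            for a in rule.antecedent.atoms():
                got = facts.get(a.fact)
                if got is None:
                    value = None if value is True else value
                    if value is False:
                        break
                elif (got == a.operand) is False:
                    value = False
                    break
            if value is None:
                continue
            applied.add(rule.rule_id)
            actions = rule.then_actions if value else rule.else_actions
            for act in actions:
                name, v = act.payload
                facts.setdefault(name, v)
            changed = True
    return facts


def _random_closure_pack(rng):
    facts = [f"f{i}" for i in range(10)]
    rules = []
    for i in range(rng.randint(1, 15)):
        literals = rng.sample(facts, rng.randint(1, 3))
        cond = all_of(*[atom(f, "eq", rng.choice([True, False])) for f in literals])
        then = (RuleAction.assert_(rng.choice(facts), True),)
        els = (RuleAction.assert_(rng.choice(facts), True),) if rng.random() < 0.4 else ()
        rules.append(Rule(f"r{i}", level=rng.randint(1, 3), category="referral_criteria",
                          antecedent=cond, then_actions=then, else_actions=els))
    return KnowledgePack("rand", "1", {f: "boolean" for f in facts}, rules,
                         conclusions=tuple(facts))


class TestOracleEquivalence:
    def test_engine_matches_brute_force_closure(self):
        """1000 random (pack, assignment) pairs; conclusions must agree."""
        rng = random.Random(42)
        for trial in range(1000):
            pack = _random_closure_pack(rng)
            inputs = {f: rng.choice([True, False])
                      for f in pack.facts if rng.random() < 0.6}
            expected = _oracle_closure(pack, inputs)
            try:
                res = infer(inputs, pack)
            except InferenceConflictError:
                continue  # oracle's setdefault policy diverges only on conflicts
            got = dict(inputs, **res.derived_facts)
            exp_true = {f for f, v in expected.items() if v is True}
            got_true = {f for f, v in got.items() if v is True}
            assert got_true == exp_true, f"trial {trial}"
            assert set(res.final_conclusions) == exp_true


class TestEngineInvariants:
    def test_single_firing_and_pass_bound(self, referral_pack, copd_facts):
        res = infer(copd_facts, referral_pack)
        ids = [f.rule_id for f in res.fired_rules]
        assert len(ids) == len(set(ids))
        assert len(ids) <= len(referral_pack.rules)
        assert max(f.iteration for f in res.fired_rules) <= len(referral_pack.rules) + 1

    def test_order_invariance_under_rule_permutation(self, copd_facts, referral_pack):
        rng = random.Random(5)
        base = infer(copd_facts, referral_pack).derived_facts
        for _ in range(5):
            shuffled = list(referral_pack.rules)
            rng.shuffle(shuffled)
            pack = KnowledgePack(referral_pack.name, referral_pack.version,
                                 referral_pack.facts, shuffled,
                                 conclusions=referral_pack.conclusions,
                                 metadata=referral_pack.metadata)
            assert infer(copd_facts, pack).derived_facts == base

    def test_irrelevant_unknown_fact_never_changes_conclusions(self, referral_pack, copd_facts):
        res_a = infer(copd_facts, referral_pack)
        res_b = infer({**copd_facts, "waiting_days": None}, referral_pack)
        assert res_a.final_conclusions == res_b.final_conclusions
        assert res_a.derived_facts == res_b.derived_facts
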