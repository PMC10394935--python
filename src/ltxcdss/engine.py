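"""Forward-chaining inference over a knowledge pack.

The engine is data-driven: in each pass it evaluates every rule that has not
yet fired, in priority order (lower priority number first, ties broken by
file order).  A rule whose antecedent is definitely true fires its *then*
actions; definitely false fires its *else* actions; unknown defers the rule
and records the blocking facts as data requests.  Iteration stops when a
full pass resolves nothing, which bounds the pass count by the rule count
(single-firing policy: a rule resolves at most once).

Because facts only accrue (a conflicting re-assertion is a hard error, never
a silent overwrite) and Kleene three-valued logic is monotone in the
information order, a definite antecedent value can never flip in a later
pass — deferring only the unknown ones is sound.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping

from .errors import InferenceConflictError
from .kb import ActionKind, KnowledgePack, Rule
from .patient import UNKNOWN, PatientStatus

__all__ = ["Severity", "Message", "RuleFiring", "InferenceResult", "infer", "explain"]


class Severity(str, Enum):
    info = "info"
    recommend = "recommend"
    alert = "alert"


@dataclass(frozen=True)
class Message:
    severity: Severity
    text: str
    rule_id: str


@dataclass(frozen=True)
class RuleFiring:
    rule_id: str
    iteration: int  # pass number, 1-based
    branch: str  # "then" | "else"
    bound_facts: tuple[tuple[str, Any], ...]  # antecedent fact snapshot at firing


@dataclass
class InferenceResult:
    input_facts: dict[str, Any]
    derived_facts: dict[str, Any] = field(default_factory=dict)
    fired_rules: list[RuleFiring] = field(default_factory=list)
    messages: list[Message] = field(default_factory=list)
    data_requests: list[str] = field(default_factory=list)
    final_conclusions: list[str] = field(default_factory=list)
    proposed_status: PatientStatus | None = None
    provenance: dict[str, str] = field(default_factory=dict)  # fact -> rule_id
    pack: KnowledgePack | None = None

    @property
    def recommendations(self) -> list[Message]:
        return [m for m in self.messages if m.severity is Severity.recommend]

    @property
    def alerts(self) -> list[Message]:
        return [m for m in self.messages if m.severity is Severity.alert]

    def fact_value(self, name: str):
        if name in self.derived_facts:
            return self.derived_facts[name]
        return self.input_facts.get(name, UNKNOWN)

    def to_json_obj(self) -> dict:
        return {
            "derived_facts": dict(self.derived_facts),
            "fired_rules": [
                {"rule_id": f.rule_id, "iteration": f.iteration, "branch": f.branch,
                 "bound_facts": dict(f.bound_facts)}
                for f in self.fired_rules
            ],
            "messages": [
                {"severity": m.severity.value, "text": m.text, "rule_id": m.rule_id}
                for m in self.messages
            ],
            "data_requests": list(self.data_requests),
            "final_conclusions": list(self.final_conclusions),
            "proposed_status": self.proposed_status.value if self.proposed_status else None,
        }


def _clean_facts(facts: Mapping[str, Any]) -> dict[str, Any]:
    """Drop explicit unknowns; absence is the canonical unknown encoding."""
    return {k: v for k, v in facts.items() if v is not UNKNOWN and v is not None}


def infer(facts: Mapping[str, Any], pack: KnowledgePack) -> InferenceResult:
    """Run forward chaining to fixpoint and return the full result + trace.

    Raises :class:`InferenceConflictError` if two rules (or a rule and an
    input fact) assert different values for the same fact — the clinical
    setting demands loud failure over arbitrary tie-breaks.
    """
    inputs = _clean_facts(facts)
    working = dict(inputs)
    result = InferenceResult(input_facts=inputs, pack=pack)
    source: dict[str, str] = {k: "input" for k in working}

    ordered = sorted(range(len(pack.rules)), key=lambda i: (pack.rules[i].effective_priority, i))
    unresolved = [pack.rules[i] for i in ordered]

    iteration = 0
    while unresolved:
        iteration += 1
        still: list[Rule] = []
        progressed = False
        for rule in unresolved:
            value = rule.antecedent.evaluate(working)
            if value is UNKNOWN:
                still.append(rule)
                continue
            progressed = True
            branch = "then" if value else "else"
            snapshot = tuple(
                (name, working.get(name, UNKNOWN)) for name in rule.antecedent.fact_names()
            )
            result.fired_rules.append(RuleFiring(rule.rule_id, iteration, branch, snapshot))
            actions = rule.then_actions if value else rule.else_actions
            for act in actions:
                _apply(act, rule, working, source, result)
        unresolved = still
        if not progressed:
            break

    # data requests: facts whose unknown-ness blocked a still-unresolved rule
    seen: dict[str, None] = {}
    for rule in unresolved:
        for name in rule.antecedent.unknown_facts(working):
            seen.setdefault(name)
    result.data_requests = list(seen)
    result.final_conclusions = [
        c for c in pack.conclusions if working.get(c, UNKNOWN) is True
    ]
    return result


def _apply(action, rule: Rule, working, source, result: InferenceResult) -> None:
    if action.kind is ActionKind.assert_fact:
        name, value = action.payload
        if name in working:
            if working[name] != value or isinstance(working[name], bool) != isinstance(value, bool):
                raise InferenceConflictError(name, working[name], source[name], value, f"rule {rule.rule_id}")
            return  # idempotent re-assertion
        working[name] = value
        result.derived_facts[name] = value
        result.provenance[name] = rule.rule_id
        source[name] = f"rule {rule.rule_id}"
    elif action.kind in (ActionKind.recommend, ActionKind.alert):
        sev = Severity.recommend if action.kind is ActionKind.recommend else Severity.alert
        result.messages.append(Message(sev, action.payload, rule.rule_id))
    elif action.kind is ActionKind.set_status:
        result.proposed_status = action.payload
    elif action.kind is ActionKind.request_data:
        for name in action.payload:
            if name not in result.data_requests:
                result.data_requests.append(name)


@dataclass
class ExplanationNode:
    """One node of an explanation tree.

    Internal nodes are facts established by a fired rule; leaves are input
    facts (or facts the antecedent read but that were never established).
    """

    fact: str
    value: Any
    rule_id: str | None = None  # None => input-fact leaf
    children: list["ExplanationNode"] = field(default_factory=list)

    def to_json_obj(self) -> dict:
        obj: dict[str, Any] = {"fact": self.fact, "value": self.value}
        if self.rule_id is None:
            obj["source"] = "input"
        else:
            obj["rule"] = self.rule_id
            obj["antecedents"] = [c.to_json_obj() for c in self.children]
        return obj

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.rule_id is None:
            return f"{pad}{self.fact} = {self.value!r}  [input]"
        lines = [f"{pad}{self.fact} = {self.value!r}  [rule {self.rule_id}]"]
        lines += [c.render(indent + 1) for c in self.children]
        return "\n".join(lines)


def explain(result: InferenceResult, conclusion: str) -> ExplanationNode:
    """Build the explanation tree for a conclusion of an inference run.

    The root is the conclusion fact, each internal node the rule that
    established a fact, and every leaf an input fact.  Raises ``KeyError``
    for a tag that is not among the result's conclusions or derived facts.
    """
    if result.pack is None:
        raise ValueError("result carries no pack; cannot explain")
    if conclusion not in result.final_conclusions and conclusion not in result.derived_facts:
        raise KeyError(f"conclusion {conclusion!r} not present in this result")
    return _explain_fact(result, conclusion, seen=set())


def _explain_fact(result: InferenceResult, fact: str, seen: set[str]) -> ExplanationNode:
    value = result.fact_value(fact)
    rule_id = result.provenance.get(fact)
    if rule_id is None or fact in seen:
        return ExplanationNode(fact=fact, value=value)
    rule = result.pack.get_rule(rule_id)
    node = ExplanationNode(fact=fact, value=value, rule_id=rule_id)
    for name in rule.antecedent.fact_names():
        node.children.append(_explain_fact(result, name, seen | {fact}))
    return node
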