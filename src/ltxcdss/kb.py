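"""Declarative IF-THEN-ELSE clinical rules: conditions, actions, knowledge packs.

A knowledge pack is data, not code: a YAML/JSON document with a fact
dictionary and an ordered rule list.  Conditions are nested ``all``/``any``/
``not``/atom nodes evaluated under Kleene three-valued logic, so a missing
fact yields *unknown* rather than false — the engine can then ask for the
missing data instead of silently rejecting a candidate.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from .errors import PackValidationError, ParseError
from .patient import UNKNOWN, PatientStatus

__all__ = [
    "Comparator",
    "Condition",
    "atom",
    "all_of",
    "any_of",
    "not_",
    "ActionKind",
    "RuleAction",
    "Rule",
    "KnowledgePack",
    "load_pack",
    "serialize_pack",
    "lint_pack",
    "LintReport",
    "builtin_referral_pack",
    "REFERRAL_CONCLUSION",
]

#: Conclusion tag asserted when the bundled pack's referral conjunction holds.
REFERRAL_CONCLUSION = "referral_criteria_met"


class Comparator(str, Enum):
    eq = "eq"
    ne = "ne"
    lt = "lt"
    le = "le"
    gt = "gt"
    ge = "ge"
    in_set = "in"


class ConditionKind(str, Enum):
    atom = "atom"
    and_ = "and"
    or_ = "or"
    not_ = "not"


@dataclass(frozen=True)
class Condition:
    """A condition tree node.

    Atoms compare one fact against an operand; composites combine children.
    Evaluation is three-valued: an atom over an unknown fact is unknown, and
    unknown propagates through and/or/not by Kleene's strong logic
    (``unknown AND false = false``, ``unknown OR true = true``,
    ``NOT unknown = unknown``).
    """

    kind: ConditionKind
    fact: str | None = None
    comparator: Comparator | None = None
    operand: Any = None
    children: tuple["Condition", ...] = ()

    def evaluate(self, facts: Mapping[str, Any]):
        """Return True, False, or UNKNOWN."""
        if self.kind is ConditionKind.atom:
            value = facts.get(self.fact, UNKNOWN)
            if value is UNKNOWN or value is None:
                return UNKNOWN
            return _compare(value, self.comparator, self.operand, self.fact)
        if self.kind is ConditionKind.not_:
            inner = self.children[0].evaluate(facts)
            return UNKNOWN if inner is UNKNOWN else (not inner)
        results = [c.evaluate(facts) for c in self.children]
        if self.kind is ConditionKind.and_:
            if any(r is False for r in results):
                return False
            if any(r is UNKNOWN for r in results):
                return UNKNOWN
            return True
        # or
        if any(r is True for r in results):
            return True
        if any(r is UNKNOWN for r in results):
            return UNKNOWN
        return False

    def atoms(self) -> list["Condition"]:
        """All atom nodes of the tree, in left-to-right order."""
        if self.kind is ConditionKind.atom:
            return [self]
        return [a for c in self.children for a in c.atoms()]

    def fact_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms():
            seen.setdefault(a.fact)
        return list(seen)

    def unknown_facts(self, facts: Mapping[str, Any]) -> list[str]:
        """Fact names of atoms that evaluate to unknown under ``facts``."""
        out: dict[str, None] = {}
        for a in self.atoms():
            if a.evaluate(facts) is UNKNOWN:
                out.setdefault(a.fact)
        return list(out)


def _compare(value, comparator: Comparator, operand, fact_name: str):
    if comparator is Comparator.eq:
        return value == operand
    if comparator is Comparator.ne:
        return value != operand
    if comparator is Comparator.in_set:
        return value in operand
    # ordering comparators require numbers
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise TypeError(
            f"ordering comparison {comparator.value!r} on non-numeric value "
            f"{value!r} for fact {fact_name!r}"
        )
    if comparator is Comparator.lt:
        return value < operand
    if comparator is Comparator.le:
        return value <= operand
    if comparator is Comparator.gt:
        return value > operand
    if comparator is Comparator.ge:
        return value >= operand
    raise ValueError(f"unknown comparator {comparator!r}")


def atom(fact: str, comparator: str | Comparator, operand) -> Condition:
    return Condition(ConditionKind.atom, fact=fact, comparator=Comparator(comparator), operand=operand)


def all_of(*children: Condition) -> Condition:
    return Condition(ConditionKind.and_, children=tuple(children))


def any_of(*children: Condition) -> Condition:
    return Condition(ConditionKind.or_, children=tuple(children))


def not_(child: Condition) -> Condition:
    return Condition(ConditionKind.not_, children=(child,))


class ActionKind(str, Enum):
    assert_fact = "assert_fact"
    recommend = "recommend"
    alert = "alert"
    set_status = "set_status"
    request_data = "request_data"


@dataclass(frozen=True)
class RuleAction:
    kind: ActionKind
    # assert_fact: (fact_name, value); recommend/alert: message string;
    # set_status: PatientStatus; request_data: tuple of fact names
    payload: Any = None

    @classmethod
    def assert_(cls, fact_name: str, value) -> "RuleAction":
        return cls(ActionKind.assert_fact, (fact_name, value))

    @classmethod
    def recommend(cls, message: str) -> "RuleAction":
        return cls(ActionKind.recommend, message)

    @classmethod
    def alert(cls, message: str) -> "RuleAction":
        return cls(ActionKind.alert, message)

    @classmethod
    def set_status(cls, status) -> "RuleAction":
        return cls(ActionKind.set_status, PatientStatus(status))

    @classmethod
    def request_data(cls, names: Iterable[str]) -> "RuleAction":
        return cls(ActionKind.request_data, tuple(names))


RULE_CATEGORIES = (
    "referral_criteria",
    "initial_assessment",
    "waiting_list_placement",
    "follow_up",
    "donor_selection",
    "committee",
)


@dataclass(frozen=True)
class Rule:
    rule_id: str
    level: int
    category: str
    antecedent: Condition
    then_actions: tuple[RuleAction, ...]
    else_actions: tuple[RuleAction, ...] = ()
    priority: int | None = None  # defaults to level

    def __post_init__(self):
        if self.level < 1:
            raise ValueError(f"rule {self.rule_id!r}: level must be >= 1")
        if self.category not in RULE_CATEGORIES:
            raise ValueError(f"rule {self.rule_id!r}: unknown category {self.category!r}")

    @property
    def effective_priority(self) -> int:
        return self.level if self.priority is None else self.priority

    def asserted_facts(self) -> list[tuple[str, Any]]:
        out = []
        for act in (*self.then_actions, *self.else_actions):
            if act.kind is ActionKind.assert_fact:
                out.append(act.payload)
        return out


@dataclass
class KnowledgePack:
    """A named, versioned bundle of facts and rules."""

    name: str
    version: str
    facts: dict[str, str]  # fact name -> value kind (boolean|number|string)
    rules: list[Rule]
    conclusions: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        violations = self._violations()
        if violations:
            raise PackValidationError(violations)

    def _violations(self) -> list[str]:
        out = []
        seen_ids: set[str] = set()
        for r in self.rules:
            if r.rule_id in seen_ids:
                out.append(f"duplicate rule_id {r.rule_id!r}")
            seen_ids.add(r.rule_id)
        for r in self.rules:
            for name in r.antecedent.fact_names():
                if name not in self.facts:
                    out.append(f"rule {r.rule_id!r} references undeclared fact {name!r}")
            for fact_name, _ in r.asserted_facts():
                if fact_name not in self.facts:
                    out.append(f"rule {r.rule_id!r} asserts undeclared fact {fact_name!r}")
            for act in (*r.then_actions, *r.else_actions):
                if act.kind is ActionKind.request_data:
                    for name in act.payload:
                        if name not in self.facts:
                            out.append(
                                f"rule {r.rule_id!r} requests undeclared fact {name!r}"
                            )
        for c in self.conclusions:
            if c not in self.facts:
                out.append(f"conclusion tag {c!r} is not a declared fact")
        return out

    def rules_in_category(self, category: str) -> list[Rule]:
        return [r for r in self.rules if r.category == category]

    def get_rule(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)


# ---------------------------------------------------------------------------
# (De)serialization
# ---------------------------------------------------------------------------

def _condition_from_obj(obj, errors: list[str], path: str) -> Condition | None:
    if not isinstance(obj, Mapping):
        errors.append(f"{path}: condition must be a mapping, got {type(obj).__name__}")
        return None
    if "all" in obj or "any" in obj:
        key = "all" if "all" in obj else "any"
        kids = [_condition_from_obj(c, errors, f"{path}.{key}[{i}]") for i, c in enumerate(obj[key])]
        if any(k is None for k in kids):
            return None
        maker = all_of if key == "all" else any_of
        return maker(*kids)
    if "not" in obj:
        kid = _condition_from_obj(obj["not"], errors, f"{path}.not")
        return not_(kid) if kid is not None else None
    if "fact" in obj:
        try:
            comp = Comparator(obj.get("op", "eq"))
        except ValueError:
            errors.append(f"{path}: unknown comparator {obj.get('op')!r}")
            return None
        operand = obj.get("value")
        if comp is Comparator.in_set and not isinstance(operand, (list, tuple)):
            errors.append(f"{path}: 'in' comparator needs a list operand")
            return None
        if comp is Comparator.in_set:
            operand = tuple(operand)
        return Condition(ConditionKind.atom, fact=obj["fact"], comparator=comp, operand=operand)
    errors.append(f"{path}: condition node needs one of 'all', 'any', 'not', 'fact'")
    return None


def _condition_to_obj(cond: Condition):
    if cond.kind is ConditionKind.atom:
        operand = list(cond.operand) if isinstance(cond.operand, tuple) else cond.operand
        return {"fact": cond.fact, "op": cond.comparator.value, "value": operand}
    if cond.kind is ConditionKind.not_:
        return {"not": _condition_to_obj(cond.children[0])}
    key = "all" if cond.kind is ConditionKind.and_ else "any"
    return {key: [_condition_to_obj(c) for c in cond.children]}


_ACTION_KEYS = {"assert", "recommend", "alert", "set_status", "request_data"}


def _action_from_obj(obj, errors: list[str], path: str) -> RuleAction | None:
    if not isinstance(obj, Mapping) or len(obj) != 1:
        errors.append(f"{path}: action must be a single-key mapping")
        return None
    (key, payload), = obj.items()
    if key == "assert":
        if not isinstance(payload, Mapping) or len(payload) != 1:
            errors.append(f"{path}: assert payload must map one fact to a value")
            return None
        (fact_name, value), = payload.items()
        return RuleAction.assert_(fact_name, value)
    if key in ("recommend", "alert"):
        return RuleAction(ActionKind(key), str(payload))
    if key == "set_status":
        try:
            return RuleAction.set_status(payload)
        except ValueError:
            errors.append(f"{path}: unknown status {payload!r}")
            return None
    if key == "request_data":
        names = payload if isinstance(payload, list) else [payload]
        return RuleAction.request_data(names)
    errors.append(f"{path}: unknown action key {key!r} (expected one of {sorted(_ACTION_KEYS)})")
    return None


def _action_to_obj(action: RuleAction):
    if action.kind is ActionKind.assert_fact:
        name, value = action.payload
        return {"assert": {name: value}}
    if action.kind is ActionKind.set_status:
        return {"set_status": action.payload.value}
    if action.kind is ActionKind.request_data:
        return {"request_data": list(action.payload)}
    return {action.kind.value: action.payload}


def load_pack(source: str | Path) -> KnowledgePack:
    """Load and validate a knowledge pack from YAML/JSON text or a file path.

    All schema violations are collected and reported together in a single
    :class:`PackValidationError`, not just the first.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    try:
        obj = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ParseError(f"pack is not well-formed YAML/JSON: {e}") from None
    if not isinstance(obj, Mapping):
        raise ParseError("pack document must be a mapping")

    errors: list[str] = []
    for required in ("name", "version", "facts"):
        if required not in obj:
            errors.append(f"missing top-level key {required!r}")
    facts = dict(obj.get("facts", {}))
    rules: list[Rule] = []
    for i, robj in enumerate(obj.get("rules", []) or []):
        path = f"rules[{i}]"
        rid = robj.get("id")
        if not rid:
            errors.append(f"{path}: missing rule id")
            continue
        cond = _condition_from_obj(robj.get("if"), errors, f"{path}.if")
        then_acts = [_action_from_obj(a, errors, f"{path}.then[{j}]") for j, a in enumerate(robj.get("then", []))]
        else_acts = [_action_from_obj(a, errors, f"{path}.else[{j}]") for j, a in enumerate(robj.get("else", []) or [])]
        if cond is None or any(a is None for a in then_acts + else_acts):
            continue
        try:
            rules.append(
                Rule(
                    rule_id=str(rid),
                    level=int(robj.get("level", 1)),
                    category=robj.get("category", "referral_criteria"),
                    antecedent=cond,
                    then_actions=tuple(then_acts),
                    else_actions=tuple(else_acts),
                    priority=robj.get("priority"),
                )
            )
        except ValueError as e:
            errors.append(f"{path}: {e}")
    if errors:
        raise PackValidationError(errors)
    return KnowledgePack(
        name=obj["name"],
        version=str(obj["version"]),
        facts=facts,
        rules=rules,
        conclusions=tuple(obj.get("conclusions", []) or []),
        metadata=dict(obj.get("metadata", {}) or {}),
    )


def serialize_pack(pack: KnowledgePack) -> str:
    """Serialize a pack back to YAML; ``load_pack`` of the result is equal."""
    rules = []
    for r in pack.rules:
        robj = {
            "id": r.rule_id,
            "level": r.level,
            "category": r.category,
            "if": _condition_to_obj(r.antecedent),
            "then": [_action_to_obj(a) for a in r.then_actions],
        }
        if r.else_actions:
            robj["else"] = [_action_to_obj(a) for a in r.else_actions]
        if r.priority is not None:
            robj["priority"] = r.priority
        rules.append(robj)
    doc = {
        "name": pack.name,
        "version": pack.version,
        "facts": dict(pack.facts),
        "conclusions": list(pack.conclusions),
        "metadata": dict(pack.metadata),
        "rules": rules,
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Linting
# ---------------------------------------------------------------------------

@dataclass
class LintReport:
    findings: list[tuple[str, str]]  # (kind, message)

    @property
    def kinds(self) -> set[str]:
        return {k for k, _ in self.findings}

    def __bool__(self):
        return bool(self.findings)


_LINT_ATOM_LIMIT = 12  # truth-table enumeration cap for overlap checks


def _antecedents_can_overlap(a: Condition, b: Condition) -> bool:
    """Can both antecedents be true at once?  Over-approximate by assigning
    truth values to the distinct atoms directly (atoms on the same fact with
    different comparators are treated as independent)."""
    atoms_a, atoms_b = a.atoms(), b.atoms()
    keyed: dict[tuple, int] = {}
    for at in atoms_a + atoms_b:
        key = (at.fact, at.comparator, at.operand if not isinstance(at.operand, tuple) else tuple(at.operand))
        keyed.setdefault(key, len(keyed))
    if len(keyed) > _LINT_ATOM_LIMIT:
        return True  # too large to enumerate; assume overlap (conservative)

    # eq-atoms on the same fact with different constants cannot both hold
    exclusive_pairs = [
        (i, j)
        for (fa, ca, va), i in keyed.items()
        for (fb, cb, vb), j in keyed.items()
        if i < j and fa == fb and ca is Comparator.eq and cb is Comparator.eq and va != vb
    ]

    def under(cond: Condition, assignment) -> bool:
        if cond.kind is ConditionKind.atom:
            key = (cond.fact, cond.comparator, cond.operand if not isinstance(cond.operand, tuple) else tuple(cond.operand))
            return assignment[keyed[key]]
        if cond.kind is ConditionKind.not_:
            return not under(cond.children[0], assignment)
        if cond.kind is ConditionKind.and_:
            return all(under(c, assignment) for c in cond.children)
        return any(under(c, assignment) for c in cond.children)

    for assignment in itertools.product([True, False], repeat=len(keyed)):
        if any(assignment[i] and assignment[j] for i, j in exclusive_pairs):
            continue
        if under(a, assignment) and under(b, assignment):
            return True
    return False


def lint_pack(pack: KnowledgePack) -> LintReport:
    """Static checks on a loaded pack; reports findings, mutates nothing.

    Flags self-dependent rules (a rule asserting a fact its own antecedent
    reads), pairs of rules that may assert contradictory values under
    jointly-satisfiable antecedents, rules with empty then and else branches,
    and rules gated on derived facts that no rule can ever produce.
    """
    findings: list[tuple[str, str]] = []
    asserted_values: dict[str, set] = {}
    for r in pack.rules:
        for name, value in r.asserted_facts():
            asserted_values.setdefault(name, set()).add(
                value if not isinstance(value, (list, dict)) else str(value)
            )

    for r in pack.rules:
        if not r.then_actions and not r.else_actions:
            findings.append(("empty-rule", f"rule {r.rule_id!r} has no then or else actions"))
        antecedent_facts = set(r.antecedent.fact_names())
        for name, _ in r.asserted_facts():
            if name in antecedent_facts:
                findings.append(("self-dependent", f"rule {r.rule_id!r} asserts fact {name!r} that its own antecedent reads"))
        # unreachable: an atom on a derived-only fact whose required value no
        # rule ever asserts (only checked when the pack declares its inputs)
        input_facts = set(pack.metadata.get("input_facts", []))
        for at in r.antecedent.atoms():
            if input_facts and at.fact not in input_facts:
                if at.fact not in asserted_values:
                    findings.append(("unreachable", f"rule {r.rule_id!r} reads fact {at.fact!r} that no rule asserts and no input provides"))
                elif at.comparator is Comparator.eq and at.operand not in asserted_values[at.fact]:
                    findings.append(("unreachable", f"rule {r.rule_id!r} needs {at.fact!r} == {at.operand!r}, which no rule asserts"))

    # pairwise contradiction check on then-branch assertions
    for ra, rb in itertools.combinations(pack.rules, 2):
        facts_a = {n: v for n, v in (act.payload for act in ra.then_actions if act.kind is ActionKind.assert_fact)}
        facts_b = {n: v for n, v in (act.payload for act in rb.then_actions if act.kind is ActionKind.assert_fact)}
        clash = {n for n in facts_a.keys() & facts_b.keys() if facts_a[n] != facts_b[n]}
        if clash and _antecedents_can_overlap(ra.antecedent, rb.antecedent):
            findings.append((
                "potential-contradiction",
                f"rules {ra.rule_id!r} and {rb.rule_id!r} may assert conflicting values for {sorted(clash)}",
            ))
    return LintReport(findings)


# ---------------------------------------------------------------------------
# Bundled referral pack
# ---------------------------------------------------------------------------

def builtin_referral_pack(
    age_min: float = 14,
    age_max: float = 65,
    fev1_comparator: str = "gt",
    fev1_threshold: float = 35.0,
) -> KnowledgePack:
    """The bundled lung-transplant referral pack.

    Encodes the published referral rule set: the age eligibility band
    (``age_min <= age <= age_max``, default 14-65), the end-stage lung
    disease criteria (ESLD, survival probability below 50%, advanced disease
    despite optimal treatment), the four mutually exclusive NYHA
    class-assignment rules, diagnosis confirmation, and the COPD-specific
    referral conjunction (FEV1 flag AND dyspnea history AND recurrent
    hospitalization AND NYHA class III/IV).

    The FEV1 threshold rule is encoded as published (``FEV1 > 35%``); both
    the comparator and the threshold are parameters because centres differ on
    the criterion's direction.
    """
    text = resources.files("ltxcdss").joinpath("packs/referral.yaml").read_text(encoding="utf-8")
    pack = load_pack(text)
    if (age_min, age_max, fev1_comparator, fev1_threshold) != (14, 65, "gt", 35.0):
        pack = _patch_thresholds(pack, age_min, age_max, fev1_comparator, fev1_threshold)
    return pack


def _patch_thresholds(pack, age_min, age_max, fev1_comparator, fev1_threshold):
    new_rules = []
    for r in pack.rules:
        if r.rule_id == "referral.age":
            cond = all_of(atom("age", "ge", age_min), atom("age", "le", age_max))
            r = replace(r, antecedent=cond)
        elif r.rule_id == "referral.copd.fev1":
            r = replace(r, antecedent=atom("fev1_pct", fev1_comparator, fev1_threshold))
        new_rules.append(r)
    return replace(pack, rules=new_rules)
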