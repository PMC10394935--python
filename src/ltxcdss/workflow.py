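"""The six-point candidate-management workflow.

Candidates move through five statuses (referred → preassessment →
referred_to_committee → waiting_list → transplanted) driven by six decision
points, each bound to one rule category of the knowledge pack:

1. referral screening        (referral_criteria, 13 decision trees)
2. initial assessment        (initial_assessment, 2 decision trees)
3. committee review          (committee)
4. waiting-list placement    (waiting_list_placement, 1 decision tree)
5. waiting-list follow-up    (follow_up, 3 decision trees; self-loop)
6. donor-day selection       (donor_selection, 1 decision tree)

Committee review and waiting-list placement share the
referred_to_committee → waiting_list edge: the committee records approval
without moving the patient, and placement executes the transition.  The
transplanted status is terminal.  Every successful transition is appended to
an audit log linked to the rule trace that produced it.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from enum import Enum

import pandas as pd

from .engine import InferenceResult, infer
from .errors import StageMismatchError, TransitionError
from .kb import KnowledgePack
from .patient import UNKNOWN, PatientRecord, PatientStatus

__all__ = [
    "DecisionPoint",
    "WorkflowConfig",
    "DEFAULT_WORKFLOW",
    "StageResult",
    "StageOutcome",
    "AuditEntry",
    "WorkflowEngine",
    "cohort_report",
]


@dataclass(frozen=True)
class DecisionPoint:
    index: int  # 1..6
    name: str
    category: str  # rule category evaluated at this point
    entry_status: PatientStatus
    success_status: PatientStatus
    failure_outcome: str  # "remain" | "exit"
    conclusion: str  # pack conclusion fact that marks success
    decision_trees: int = 0  # published decision-tree count for the category


@dataclass(frozen=True)
class WorkflowConfig:
    points: tuple[DecisionPoint, ...]
    edges: frozenset[tuple[PatientStatus, PatientStatus]]

    def __post_init__(self):
        if [p.index for p in self.points] != list(range(1, len(self.points) + 1)):
            raise ValueError("decision point indices must be 1..n consecutive")
        if len(self.points) != 6:
            raise ValueError("the decision model has exactly six points")
        # transplanted is terminal
        for a, b in self.edges:
            if a is PatientStatus.transplanted:
                raise ValueError("transplanted is terminal; no outgoing edges allowed")
        # acyclic apart from the follow-up self-loop on waiting_list
        non_loop = {(a, b) for a, b in self.edges if a is not b}
        order = list(PatientStatus)
        rank = {s: i for i, s in enumerate(order)}
        for a, b in non_loop:
            if rank[b] <= rank[a]:
                raise ValueError(f"edge {a.value} -> {b.value} goes against the workflow order")

    def point(self, index: int) -> DecisionPoint:
        return self.points[index - 1]

    def allows(self, a: PatientStatus, b: PatientStatus) -> bool:
        return (a, b) in self.edges


def _default_points() -> tuple[DecisionPoint, ...]:
    S = PatientStatus
    return (
        DecisionPoint(1, "referral screening", "referral_criteria", S.referred, S.preassessment, "exit", "referral_criteria_met", 13),
        DecisionPoint(2, "initial assessment", "initial_assessment", S.preassessment, S.referred_to_committee, "exit", "initial_assessment_passed", 2),
        DecisionPoint(3, "committee review", "committee", S.referred_to_committee, S.referred_to_committee, "exit", "waitlist_approved", 0),
        DecisionPoint(4, "waiting-list placement", "waiting_list_placement", S.referred_to_committee, S.waiting_list, "remain", "waitlisted", 1),
        DecisionPoint(5, "waiting-list follow-up", "follow_up", S.waiting_list, S.waiting_list, "exit", "follow_up_ok", 3),
        DecisionPoint(6, "donor-day selection", "donor_selection", S.waiting_list, S.transplanted, "remain", "transplant_confirmed", 1),
    )


DEFAULT_WORKFLOW = WorkflowConfig(
    points=_default_points(),
    edges=frozenset({
        (PatientStatus.referred, PatientStatus.preassessment),
        (PatientStatus.preassessment, PatientStatus.referred_to_committee),
        (PatientStatus.referred_to_committee, PatientStatus.waiting_list),
        (PatientStatus.waiting_list, PatientStatus.waiting_list),  # follow-up loop
        (PatientStatus.waiting_list, PatientStatus.transplanted),
    }),
)


class StageResult(str, Enum):
    passed = "passed"
    failed = "failed"
    needs_data = "needs_data"


@dataclass
class StageOutcome:
    point: DecisionPoint
    result: StageResult
    inference: InferenceResult
    proposed_status: PatientStatus
    exit_reason: str | None = None
    patient_id: str | None = None


@dataclass(frozen=True)
class AuditEntry:
    timestamp: str
    patient_id: str
    point_index: int
    from_status: PatientStatus
    to_status: PatientStatus
    fired_rules: tuple[str, ...]


class WorkflowEngine:
    """Evaluates decision points and advances candidate status.

    Holds the workflow configuration and an append-only audit log; one entry
    is written per successful advance.
    """

    def __init__(self, pack: KnowledgePack, config: WorkflowConfig = DEFAULT_WORKFLOW):
        self.pack = pack
        self.config = config
        self.audit: list[AuditEntry] = []

    def evaluate_stage(self, record: PatientRecord, point: DecisionPoint | int) -> StageOutcome:
        """Run the point's rule category against the record's facts.

        The record's status must equal the point's entry status.  The outcome
        is *passed* when the point's conclusion fact is established true,
        *failed* when definitely false, and *needs_data* when unknown facts
        blocked a definite answer (status unchanged).
        """
        if isinstance(point, int):
            point = self.config.point(point)
        if record.status is not point.entry_status:
            raise StageMismatchError(
                f"patient {record.patient_id!r} has status {record.status.value!r} but "
                f"decision point {point.index} ({point.name}) requires {point.entry_status.value!r}"
            )
        rules = self.pack.rules_in_category(point.category)
        sub = replace(self.pack, rules=rules)
        res = infer(record.all_facts(), sub)
        if not rules:
            # empty extension-point category (follow-up): nothing to check
            return StageOutcome(point, StageResult.passed, res, point.success_status,
                                patient_id=record.patient_id)
        value = res.fact_value(point.conclusion)
        if value is True:
            return StageOutcome(point, StageResult.passed, res, point.success_status,
                                patient_id=record.patient_id)
        if value is UNKNOWN and res.data_requests:
            return StageOutcome(point, StageResult.needs_data, res, record.status,
                                patient_id=record.patient_id)
        reason = None
        if point.failure_outcome == "exit":
            alerts = [m.text for m in res.alerts]
            reason = alerts[0] if alerts else f"failed {point.name}"
        return StageOutcome(point, StageResult.failed, res, record.status,
                            exit_reason=reason, patient_id=record.patient_id)

    def advance(self, record: PatientRecord, outcome: StageOutcome) -> PatientRecord:
        """Apply a stage outcome: move to the proposed status along a legal edge.

        Returns a new record; appends an audit entry when the status actually
        changes.  Failed or needs-data outcomes leave the record unchanged.
        """
        if outcome.patient_id != record.patient_id:
            raise TransitionError(
                f"outcome was produced for patient {outcome.patient_id!r}, not {record.patient_id!r}"
            )
        if outcome.result is not StageResult.passed:
            return record
        target = outcome.proposed_status
        if target is record.status:
            return record
        if record.status is PatientStatus.transplanted:
            raise TransitionError("transplanted is a terminal status")
        if not self.config.allows(record.status, target):
            raise TransitionError(
                f"illegal transition {record.status.value} -> {target.value} "
                f"at decision point {outcome.point.index}"
            )
        self.audit.append(AuditEntry(
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
            patient_id=record.patient_id,
            point_index=outcome.point.index,
            from_status=record.status,
            to_status=target,
            fired_rules=tuple(f.rule_id for f in outcome.inference.fired_rules),
        ))
        return replace(record, status=target)


def cohort_report(records: list[PatientRecord]) -> pd.DataFrame:
    """Status and blood-group frequency table with one-decimal percentages.

    Columns: variable, value, count, percent.  Counts within each variable
    sum to the cohort size.
    """
    rows = []
    n = len(records)
    if n == 0:
        return pd.DataFrame(columns=["variable", "value", "count", "percent"])

    def block(variable: str, values: list[str]):
        counts: dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        for v, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append({
                "variable": variable, "value": v, "count": c,
                "percent": round(100.0 * c / n, 1),
            })

    block("sex", [r.sex or "unknown" for r in records])
    block("status", [r.status.value for r in records])
    block("blood_group", [str(r.blood_group) if r.blood_group else "unknown" for r in records])
    return pd.DataFrame(rows)
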