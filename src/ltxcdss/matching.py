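"""Donor-to-candidate blood-group matching for donor-day selection.

Implements the standard ABO compatibility matrix (donor → recipient:
O→{O,A,B,AB}, A→{A,AB}, B→{B,AB}, AB→{AB}) with optional Rh enforcement
(an Rh-positive donor restricted to Rh-positive recipients; Rh-negative
donors give to anyone).  Only waiting-list patients are ever eligible.

The conservative default policy is identical-group, Rh-strict; compatible
matching is available as a policy switch.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

from .patient import BloodGroup, PatientRecord, PatientStatus, Rh, parse_blood_group

__all__ = [
    "DonorDescriptor",
    "MatchMode",
    "CompatibilityPolicy",
    "MatchedCandidate",
    "abo_compatible",
    "rh_compatible",
    "eligible_candidates",
]

# donor ABO -> recipient ABO sets
_ABO_MATRIX = {
    "O": {"O", "A", "B", "AB"},
    "A": {"A", "AB"},
    "B": {"B", "AB"},
    "AB": {"AB"},
}


def abo_compatible(donor: BloodGroup, recipient: BloodGroup) -> bool:
    return recipient.abo.value in _ABO_MATRIX[donor.abo.value]


def rh_compatible(donor: BloodGroup, recipient: BloodGroup) -> bool:
    """Rh-negative donors are universal; Rh-positive require Rh-positive."""
    return donor.rh is Rh.negative or recipient.rh is Rh.positive


class MatchMode(str, Enum):
    identical_only = "identical_only"
    abo_compatible = "abo_compatible"


@dataclass(frozen=True)
class CompatibilityPolicy:
    mode: MatchMode = MatchMode.identical_only
    rh_strict: bool = True


@dataclass(frozen=True)
class DonorDescriptor:
    donor_id: str
    blood_group: BloodGroup
    attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.blood_group, str):
            object.__setattr__(self, "blood_group", parse_blood_group(self.blood_group))


@dataclass(frozen=True)
class MatchedCandidate:
    record: PatientRecord
    identical: bool  # exact same ABO/Rh group as the donor
    rationale: str


def _compatible(donor: BloodGroup, recipient: BloodGroup, policy: CompatibilityPolicy) -> bool:
    if policy.mode is MatchMode.identical_only:
        if donor.abo is not recipient.abo:
            return False
        return (donor.rh is recipient.rh) if policy.rh_strict else True
    if not abo_compatible(donor, recipient):
        return False
    return rh_compatible(donor, recipient) if policy.rh_strict else True


def eligible_candidates(
    donor: DonorDescriptor,
    cohort: list[PatientRecord],
    policy: CompatibilityPolicy = CompatibilityPolicy(),
) -> list[MatchedCandidate]:
    """Waiting-list patients compatible with the donor, best match first.

    Ordering: identical blood group before merely compatible; within a tier,
    longer waiting time first (numeric fact ``waiting_days`` if present);
    remaining ties by patient_id.  An empty list is a valid outcome.
    """
    out: list[MatchedCandidate] = []
    for rec in cohort:
        if rec.status is not PatientStatus.waiting_list or rec.blood_group is None:
            continue
        if not _compatible(donor.blood_group, rec.blood_group, policy):
            continue
        identical = rec.blood_group == donor.blood_group
        rationale = (
            f"recipient {rec.blood_group} {'identical to' if identical else 'compatible with'} "
            f"donor {donor.blood_group} under {policy.mode.value}"
            f"{', Rh-strict' if policy.rh_strict else ''}"
        )
        out.append(MatchedCandidate(rec, identical, rationale))

    def sort_key(mc: MatchedCandidate):
        waiting = mc.record.facts.get("waiting_days")
        waiting = waiting if isinstance(waiting, (int, float)) and not isinstance(waiting, bool) else 0
        return (0 if mc.identical else 1, -waiting, mc.record.patient_id)

    out.sort(key=sort_key)
    return out
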