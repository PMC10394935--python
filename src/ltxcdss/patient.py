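"""Patient fact model: blood groups, candidate status, records, and data schemas.

Facts use three-valued semantics throughout the package: a fact absent from a
record is *unknown*, never silently false.  ``UNKNOWN`` is the explicit
sentinel; downstream rule evaluation propagates it (Kleene logic).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping

from .errors import ParseError

__all__ = [
    "UNKNOWN",
    "ABO",
    "Rh",
    "BloodGroup",
    "PatientStatus",
    "PatientRecord",
    "SchemaItem",
    "DataSchema",
    "ItemStatus",
    "ValidationReport",
    "parse_blood_group",
    "validate_record",
]


class _Unknown:
    """Singleton sentinel for a fact whose value has not been established."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNKNOWN"

    def __bool__(self):
        raise TypeError("UNKNOWN has no truth value; handle it explicitly")


#: The single unknown-fact sentinel.
UNKNOWN = _Unknown()


class ABO(str, Enum):
    O = "O"
    A = "A"
    B = "B"
    AB = "AB"


class Rh(str, Enum):
    positive = "+"
    negative = "-"


@dataclass(frozen=True, order=True)
class BloodGroup:
    """One of the eight ABO/Rh groups (O+, O-, A+, A-, B+, B-, AB+, AB-)."""

    abo: ABO
    rh: Rh

    def __str__(self) -> str:
        return f"{self.abo.value}{self.rh.value}"

    @classmethod
    def all_groups(cls) -> list["BloodGroup"]:
        return [cls(a, r) for a in ABO for r in Rh]


# Unicode minus / dash variants accepted on input, normalised to ASCII "-".
_MINUS_VARIANTS = "−–—‐‑"


def parse_blood_group(text: str) -> BloodGroup:
    """Parse a blood-group string such as ``"AB+"`` or ``"O-"``.

    Accepts the eight canonical forms, case-insensitively, with Unicode
    minus/dash variants for the negative sign.  Raises :class:`ParseError`
    naming the offending input otherwise.
    """
    if not isinstance(text, str):
        raise ParseError(f"blood group must be a string, got {type(text).__name__}")
    cleaned = text.strip()
    for ch in _MINUS_VARIANTS:
        cleaned = cleaned.replace(ch, "-")
    if len(cleaned) < 2:
        raise ParseError(f"unrecognized blood group: {text!r}")
    abo_part, rh_part = cleaned[:-1].upper(), cleaned[-1]
    try:
        abo = ABO(abo_part)
    except ValueError:
        raise ParseError(f"unrecognized blood group: {text!r}") from None
    if rh_part == "+":
        rh = Rh.positive
    elif rh_part == "-":
        rh = Rh.negative
    else:
        raise ParseError(f"unrecognized blood group: {text!r}")
    return BloodGroup(abo, rh)


class PatientStatus(str, Enum):
    """The five workflow statuses a transplant candidate can hold."""

    referred = "referred"
    preassessment = "preassessment"
    referred_to_committee = "referred_to_committee"
    waiting_list = "waiting_list"
    transplanted = "transplanted"


FactValue = Any  # bool | int | float | str | UNKNOWN


@dataclass
class PatientRecord:
    """Facts about one candidate.

    ``facts`` maps fact names to values; a name that is absent is unknown.
    ``age``, ``sex``, ``diagnosis`` and ``blood_group`` are mirrored into the
    fact map under their own names so rules can reference them uniformly.
    """

    patient_id: str
    age: float | None = None
    sex: str | None = None  # "male" | "female"
    diagnosis: str | None = None
    blood_group: BloodGroup | None = None
    status: PatientStatus = PatientStatus.referred
    facts: dict[str, FactValue] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.age is not None:
            if not (isinstance(self.age, (int, float)) and math.isfinite(self.age)):
                raise ValueError(f"age must be a finite number, got {self.age!r}")
            if self.age < 0:
                raise ValueError(f"age must be non-negative, got {self.age!r}")
        if isinstance(self.status, str) and not isinstance(self.status, PatientStatus):
            self.status = PatientStatus(self.status)
        if isinstance(self.blood_group, str):
            self.blood_group = parse_blood_group(self.blood_group)

    def all_facts(self) -> dict[str, FactValue]:
        """The fact map with demographic attributes folded in."""
        merged = dict(self.facts)
        if self.age is not None:
            merged.setdefault("age", self.age)
        if self.sex is not None:
            merged.setdefault("sex", self.sex)
        if self.diagnosis is not None:
            merged.setdefault("diagnosis", self.diagnosis)
        if self.blood_group is not None:
            merged.setdefault("blood_group", str(self.blood_group))
        return merged

    @classmethod
    def from_json(cls, text_or_obj) -> "PatientRecord":
        obj = json.loads(text_or_obj) if isinstance(text_or_obj, str) else dict(text_or_obj)
        return cls(
            patient_id=obj["patient_id"],
            age=obj.get("age"),
            sex=obj.get("sex"),
            diagnosis=obj.get("diagnosis"),
            blood_group=obj.get("blood_group"),
            status=PatientStatus(obj.get("status", "referred")),
            facts=dict(obj.get("facts", {})),
            categories=dict(obj.get("categories", {})),
        )

    def to_json_obj(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "age": self.age,
            "sex": self.sex,
            "diagnosis": self.diagnosis,
            "blood_group": str(self.blood_group) if self.blood_group else None,
            "status": self.status.value,
            "facts": {k: (None if v is UNKNOWN else v) for k, v in self.facts.items()},
        }


# Placeholder names for the eight data-item domains of the minimum data set;
# user-replaceable, see DataSchema.
DEFAULT_CATEGORIES = tuple(f"domain_{i}" for i in range(1, 9))

_VALUE_KINDS = {"boolean", "number", "string"}


@dataclass(frozen=True)
class SchemaItem:
    name: str
    kind: str  # boolean | number | string
    category: str

    def __post_init__(self):
        if self.kind not in _VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.kind!r} for item {self.name!r}")


class ItemStatus(str, Enum):
    present_valid = "present-valid"
    present_invalid = "present-invalid"
    missing = "missing"


@dataclass
class DataSchema:
    """An ordered minimum data set: items with value kinds, grouped in domains."""

    items: list[SchemaItem]
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self):
        names = [it.name for it in self.items]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate schema item names: {sorted(dupes)}")
        bad = [it.name for it in self.items if it.category not in self.categories]
        if bad:
            raise ValueError(f"items in undeclared categories: {bad}")

    @classmethod
    def from_obj(cls, obj: Mapping) -> "DataSchema":
        cats = tuple(obj.get("categories", DEFAULT_CATEGORIES))
        items = [
            SchemaItem(d["name"], d.get("kind", "string"), d.get("category", cats[0]))
            for d in obj["items"]
        ]
        return cls(items=items, categories=cats)


def _kind_ok(value: FactValue, kind: str) -> bool:
    if kind == "boolean":
        return isinstance(value, bool)
    if kind == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool) and math.isfinite(value)
    return isinstance(value, str)


@dataclass
class ValidationReport:
    item_status: dict[str, ItemStatus]
    completeness: float

    @property
    def missing_items(self) -> list[str]:
        return [n for n, s in self.item_status.items() if s is ItemStatus.missing]

    @property
    def invalid_items(self) -> list[str]:
        return [n for n, s in self.item_status.items() if s is ItemStatus.present_invalid]


def validate_record(record: PatientRecord, schema: DataSchema) -> ValidationReport:
    """Check a record against a schema, item by item.

    Each item is present-valid, present-invalid (wrong value kind — reported,
    never raised), or missing (absent or explicitly unknown).  Completeness is
    the present-valid fraction of all schema items.
    """
    if not schema.items:
        raise ValueError("schema must contain at least one item")
    facts = record.all_facts()
    statuses: dict[str, ItemStatus] = {}
    for item in schema.items:
        value = facts.get(item.name, UNKNOWN)
        if value is UNKNOWN or value is None:
            statuses[item.name] = ItemStatus.missing
        elif _kind_ok(value, item.kind):
            statuses[item.name] = ItemStatus.present_valid
        else:
            statuses[item.name] = ItemStatus.present_invalid
    valid = sum(1 for s in statuses.values() if s is ItemStatus.present_valid)
    return ValidationReport(item_status=statuses, completeness=valid / len(schema.items))
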