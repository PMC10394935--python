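"""Exception hierarchy shared across the package."""


class LtxCdssError(Exception):
    """Base class for all package errors."""


class ParseError(LtxCdssError):
    """Malformed input text (blood group, pack file, record file)."""


class PackValidationError(LtxCdssError):
    """A knowledge pack violates its schema or internal invariants.

    Carries the full list of violations, not just the first one found.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "pack validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class InferenceConflictError(LtxCdssError):
    """Two rules (or a rule and an input fact) assert conflicting values."""

    def __init__(self, fact_name, value_a, source_a, value_b, source_b):
        self.fact_name = fact_name
        self.sources = (source_a, source_b)
        super().__init__(
            f"conflicting values for fact {fact_name!r}: "
            f"{value_a!r} from {source_a} vs {value_b!r} from {source_b}"
        )


class TransitionError(LtxCdssError):
    """An illegal patient-status transition was requested."""


class StageMismatchError(LtxCdssError):
    """Patient status does not match a decision point's entry status."""


class UndefinedMetricError(LtxCdssError):
    """A confusion-matrix metric has a zero denominator."""


class DegenerateInputError(LtxCdssError):
    """Statistical input admits no meaningful answer (e.g. zero variance)."""
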