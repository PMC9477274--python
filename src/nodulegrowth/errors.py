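"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`NoduleGrowthError`, so callers can catch one base class at the
pipeline boundary.
"""


class NoduleGrowthError(Exception):
    """Base class for all errors raised by nodulegrowth."""


class InvalidMeasurementError(NoduleGrowthError, ValueError):
    """A measurement violates its physical constraints (e.g. volume <= 0)."""


class InsufficientDataError(NoduleGrowthError, ValueError):
    """An operation needs a field (e.g. a reader call) that is missing."""


class EmptyInputError(NoduleGrowthError, ValueError):
    """An operation received an empty collection."""


class UndefinedProportionError(NoduleGrowthError, ZeroDivisionError):
    """A proportion was requested with a zero denominator."""


class DegenerateLabelsError(NoduleGrowthError, ValueError):
    """A two-class statistic was requested on single-class labels."""


class DegenerateCohortError(NoduleGrowthError, ValueError):
    """The cohort cannot support the requested analysis (e.g. one class only)."""


class ConfigValidationError(NoduleGrowthError, ValueError):
    """Simulation configuration invalid; lists the offending fields."""

    def __init__(self, fields: list[str]):
        self.fields = list(fields)
        super().__init__("invalid configuration fields: " + ", ".join(self.fields))


class CohortValidationError(NoduleGrowthError, ValueError):
    """Cohort CSV failed schema validation; carries per-row messages."""

    def __init__(self, row_errors: list[str]):
        self.row_errors = list(row_errors)
        msg = "\n".join(self.row_errors)
        super().__init__(f"cohort validation failed ({len(self.row_errors)} problems):\n{msg}")
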