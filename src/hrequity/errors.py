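"""Exception hierarchy for the equity pipeline.

Every error raised on purpose by this package derives from
:class:`EquityError`, so callers can catch pipeline failures without
catching programming errors.
"""


class EquityError(Exception):
    """Base class for all errors raised by hrequity."""


class PanelSchemaError(EquityError):
    """The input table is structurally wrong (missing/unknown columns)."""


class PanelValidationError(EquityError):
    """A cell value violates the panel invariants (sign, type, coverage)."""


class DuplicateRecordError(PanelValidationError):
    """More than one observation for the same (region, year)."""


class UndefinedStatisticError(EquityError):
    """A statistic is undefined for the given inputs (e.g. zero totals).

    Raised instead of silently returning 0, inf or NaN.
    """


class DegenerateMatrixError(EquityError):
    """The decision matrix carries no usable information (uniform columns)."""


class MissingYearError(EquityError):
    """A requested year is absent from the panel."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"panel does not cover year(s): {self.missing}")


class StageError(EquityError):
    """A pipeline stage failed; carries the stage name, chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
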