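"""Exception hierarchy for ventassess.

All package errors derive from :class:`VentAssessError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class VentAssessError(Exception):
    """Base class for all ventassess errors."""


class ValidationError(VentAssessError):
    """Invalid input data (bad coordinate, duplicate id, missing column).

    Carries optional ``row`` (1-based data row number) and ``field`` context
    so file readers can report precise provenance.
    """

    def __init__(self, message: str, *, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


class NoOccurrenceRecordsError(VentAssessError):
    """Raised when an operation requires at least one occurrence record.

    Callers performing a full assessment map this to a Data Deficient (DD)
    outcome rather than a crash.
    """

    def __init__(self, message: str = "no occurrence records"):
        super().__init__(message)


class ConfigurationError(VentAssessError):
    """A referenced management area, regime token or config value is unknown."""


class InfeasibleSpecError(VentAssessError):
    """A synthetic-ridge specification cannot be realised (e.g. jitter too
    large relative to spacing for the requested cluster structure)."""
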