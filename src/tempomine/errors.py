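"""Exception hierarchy shared across tempomine modules."""


class TempomineError(Exception):
    """Base class for all package errors."""


class FormatError(TempomineError):
    """Input file is structurally malformed (missing columns, bad header)."""


class RowValidationError(TempomineError):
    """One or more data rows failed validation.

    Carries the offending row numbers (1-based, header excluded) and a
    per-row message so callers can report rather than silently drop them.
    """

    def __init__(self, problems):
        self.problems = list(problems)  # list of (row_number, message)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.problems)
        super().__init__(f"{len(self.problems)} row(s) failed validation: {lines}")


class ConfigurationError(TempomineError):
    """Invalid configuration (missing reference range, bad threshold)."""


class UndefinedInputError(TempomineError):
    """An operation was called on input for which it is undefined
    (e.g. support of an itemset over zero transactions)."""


class InsufficientDataError(TempomineError):
    """A series is too short for the requested computation."""


class InversionError(TempomineError):
    """The rule-metric table could not be inverted into consistent counts."""


class ConstructionError(TempomineError):
    """The deterministic fixture builder violated a count constraint."""
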