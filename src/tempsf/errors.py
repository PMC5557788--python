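"""Exception hierarchy for tempsf."""


class TempSFError(Exception):
    """Base class for all tempsf errors."""


class ParseError(TempSFError):
    """A text input could not be parsed; carries the offending line/row."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(TempSFError):
    """Input data violates an invariant (ordering, finiteness, sign)."""


class InsufficientDataError(TempSFError):
    """Too few samples/scales for the requested operation."""


class ScaleRangeError(TempSFError):
    """Requested scale range incompatible with the series or SF grid."""


class ParameterError(TempSFError):
    """An operation parameter is out of its valid domain."""


class DegenerateSignalError(TempSFError):
    """The signal is constant (or otherwise degenerate) at the scales probed."""


class IncompatibilityError(TempSFError):
    """Two results cannot be combined (e.g., plateau windows differ)."""


class InstabilityError(TempSFError):
    """A numerical integration blew up; typically the step size is too large."""
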