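"""Exception hierarchy for the vhitdrift package."""


class VhitError(Exception):
    """Base class for all vhitdrift errors."""


class InputError(VhitError):
    """Invalid or inconsistent input data."""


class RecordingParseError(VhitError):
    """A recording file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ProtocolError(VhitError):
    """A recording could not be assigned to a test protocol."""


class DegenerateMaskError(VhitError):
    """A rest mask has fewer than two samples; masked statistics undefined."""


class UndefinedCorrelationError(VhitError):
    """Correlation is undefined (constant input, insufficient sample)."""


class OptimizationError(VhitError):
    """The optimizer encountered a non-finite objective.

    The partial trace accumulated so far is attached as ``trace``.
    """

    def __init__(self, message: str, trace=None):
        self.trace = trace
        super().__init__(message)
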