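"""Exception hierarchy shared across the package."""


class SignalflipError(Exception):
    """Base class for all package errors."""


class NetworkParseError(SignalflipError):
    """A network file row could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ParameterError(SignalflipError):
    """A numeric parameter violates its precondition."""


class InputError(SignalflipError):
    """User-supplied data is inconsistent (missing genes, disjoint sets...)."""
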