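"""Exception hierarchy shared across the package."""


class CoevomiError(Exception):
    """Base class for all package-specific errors."""


class InputError(CoevomiError, ValueError):
    """Invalid argument values or inconsistent inputs (precondition failures)."""


class AlignmentError(InputError):
    """Sequences that do not form a valid alignment (e.g. ragged lengths)."""


class ParseError(CoevomiError, ValueError):
    """Malformed file content; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
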