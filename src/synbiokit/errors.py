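"""Exception hierarchy shared across the toolkit.

``SynbioValidationError`` maps to CLI exit code 1, I/O problems
(``OSError``) to exit code 2.
"""


class SynbioError(Exception):
    """Base class for all toolkit errors."""


class SynbioParseError(SynbioError, ValueError):
    """Input text does not parse in the expected dialect.

    Where possible the message names the offending line number or token
    position.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line})"
        elif column is not None:
            loc = f" (position {column})"
        super().__init__(message + loc)
        self.line = line
        self.column = column


class SynbioValidationError(SynbioError, ValueError):
    """Structurally parsed input violates a domain invariant."""
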