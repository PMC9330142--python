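"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class MtoopError(Exception):
    """Base class for all package errors."""


class ConfigError(MtoopError):
    """Invalid or inconsistent configuration."""


class DataError(MtoopError):
    """Problem with input data."""


class ParseError(DataError):
    """A file could not be parsed; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx += f" [{path}"
            ctx += f":{line}]" if line is not None else "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line


class ValidationError(DataError):
    """Structurally parseable input violating a domain invariant."""
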