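"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3.
"""


class FisherseqError(Exception):
    """Base class for all package errors."""


class ConfigError(FisherseqError):
    """Invalid configuration (bad paths, out-of-range parameters)."""


class DataError(FisherseqError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """Malformed record in an input stream; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
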