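"""Exception types shared across the package."""


class PvSignalError(Exception):
    """Base class for all package errors."""


class SchemaError(PvSignalError):
    """A file header does not match any known table schema."""


class ParseError(PvSignalError):
    """A data line cannot be parsed (e.g. ragged row)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigurationError(PvSignalError):
    """Invalid or missing configuration (dictionary, map, thresholds...)."""


class PipelineError(PvSignalError):
    """A pipeline stage cannot proceed (e.g. no target-drug reports)."""
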