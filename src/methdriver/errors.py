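"""Exception hierarchy shared across the pipeline."""


class MethdriverError(Exception):
    """Base class for all pipeline errors."""


class ParseError(MethdriverError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(MethdriverError):
    """Input parsed but violates an invariant (negative counts, duplicate ids, ...)."""


class ConfigurationError(MethdriverError):
    """A configuration references entities that do not exist or are inconsistent."""


class SizingError(MethdriverError):
    """A simulated chromosome is too short for the requested content."""
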