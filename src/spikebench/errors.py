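"""Exception types shared across the package."""


class SpikebenchError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpikebenchError, ValueError):
    """A numeric parameter is out of its admissible range."""


class ConfigurationError(SpikebenchError, ValueError):
    """A configuration value (backend name, protocol name, ...) is unknown
    or inconsistent."""


class UnsupportedDelayError(SpikebenchError, ValueError):
    """A transmission delay exceeds what one delay-extension stage plus the
    16-slot ring buffer can represent."""


class ParseError(SpikebenchError, ValueError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
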