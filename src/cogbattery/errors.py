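"""Exception hierarchy for the battery."""


class BatteryError(Exception):
    """Base class for all package-specific errors."""


class GenerationError(BatteryError):
    """A stochastic schedule generator exhausted its rejection/restart budget."""


class ValidationError(BatteryError):
    """An emitted schedule or session violates a structural invariant."""


class EstimationError(BatteryError):
    """A posterior cannot be estimated from the data provided."""


class ConfigError(BatteryError):
    """A configuration document is malformed or incomplete."""


class SchemaError(BatteryError):
    """A serialized file does not follow the pinned schema."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
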