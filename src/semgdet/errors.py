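"""Exception hierarchy shared across the pipeline."""


class SemgdetError(Exception):
    """Base class for all package errors."""


class DomainError(SemgdetError, ValueError):
    """An argument is outside its physical/mathematical domain."""


class ConfigError(SemgdetError, ValueError):
    """A configuration value is invalid or inconsistent."""


class ValidationError(SemgdetError, ValueError):
    """Structured input failed validation."""


class RangeError(SemgdetError, ValueError):
    """A requested window or index lies outside the data."""


class NoLabelError(SemgdetError, ValueError):
    """A record contains no detectable action, so no box label exists."""


class LabelSchemaError(SemgdetError, ValueError):
    """A JSON label file violates the label schema."""


class ConstructionError(SemgdetError, ValueError):
    """A network cannot be built from the given block specification."""


class DependencyError(SemgdetError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
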