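"""Exception and warning types shared across the package."""


class HzrdError(Exception):
    """Base class for package errors."""


class ConfigError(HzrdError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(HzrdError, ValueError):
    """A person table does not conform to the expected schema."""


class DomainError(HzrdError, ValueError):
    """An input (e.g. a date of birth) lies outside the supported domain."""


class DataIntegrityError(HzrdError, ValueError):
    """A person record is internally inconsistent (e.g. events after death)."""


class EstimationError(HzrdError, RuntimeError):
    """An estimator cannot be computed on the given data."""


class WeakInstrumentError(EstimationError):
    """First-stage discontinuity below the guard threshold."""


class BandwidthFallbackWarning(UserWarning):
    """Plug-in bandwidth selection fell back to a rule of thumb."""


class DegenerateSplitWarning(UserWarning):
    """A median split produced a degenerate (single-group) partition."""
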