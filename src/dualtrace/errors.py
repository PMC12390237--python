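"""Exception hierarchy for the dualtrace pipeline.

All pipeline-specific failures derive from :class:`DualTraceError` so that
callers (and the CLI) can distinguish domain errors from programming bugs.
Scalar-argument domain violations raise plain :class:`ValueError`.
"""


class DualTraceError(Exception):
    """Base class for all dualtrace errors."""


class SchemaError(DualTraceError):
    """A tabular input does not match the documented column schema."""


class DataValidationError(DualTraceError):
    """A table row violates an invariant (unknown group/day, negative value...)."""


class MissingControlError(DualTraceError):
    """The measurement table contains no control-group rows."""


class InsufficientDataError(DualTraceError):
    """Too few observations / distinct design points for the requested estimate."""


class DegenerateDesignError(InsufficientDataError):
    """Zero variance in the regressor: the slope is not identifiable."""


class ConfigurationError(DualTraceError):
    """An analysis or simulation configuration is internally inconsistent."""


class PairingError(DualTraceError):
    """Two per-cell results that must refer to the same group x day do not."""


class DependencyError(DualTraceError):
    """A report stage was requested before its upstream stage output exists."""
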