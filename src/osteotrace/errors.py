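"""Structured exceptions shared across the package."""


class OsteotraceError(Exception):
    """Base class for all package errors."""


class DegenerateCloudError(OsteotraceError):
    """Point cloud has no dominant principal axis (rank < 3 or ratio test fails)."""


class ValidationError(OsteotraceError):
    """A record or argument violates an invariant."""


class OffTemplateError(ValidationError):
    """Mark position falls outside the (expanded) template bounding box."""


class UnknownFilterError(ValidationError):
    """Query used a filter key that is not supported."""


class EmptyCropError(ValidationError):
    """A crop operation retained zero template points."""


class EstimatorError(OsteotraceError):
    """A summary-function estimator received incompatible input."""
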