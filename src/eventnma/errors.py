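"""Exception hierarchy for the pipeline.

Every error raised by this package derives from :class:`EventNmaError`, so
callers can catch pipeline failures without masking programming errors.
"""


class EventNmaError(Exception):
    """Base class for all package errors."""


class SchemaError(EventNmaError):
    """An input table does not match the documented column schema."""


class DataError(EventNmaError):
    """A record violates a data invariant (e.g. more events than patients)."""


class CodingError(EventNmaError):
    """A treatment code is unknown or the coding table is inconsistent."""


class ConfigurationError(EventNmaError):
    """A model/analysis configuration is internally inconsistent."""


class EstimabilityError(EventNmaError):
    """The evidence network is disconnected for the requested analysis."""


class ComparisonError(EventNmaError):
    """Model-fit statistics being compared were not computed on the same data."""


class ReportingError(EventNmaError):
    """A report was requested from an incomplete or invalid run directory."""
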