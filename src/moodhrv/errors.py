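"""Exception types shared across the pipeline.

All inherit from :class:`MoodHRVError` so callers can catch pipeline errors
as a family; most are also ``ValueError`` subclasses since they signal bad
inputs rather than internal faults.
"""


class MoodHRVError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MoodHRVError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DomainError(MoodHRVError, ValueError):
    """A value outside its documented domain (scale range, probability, ...)."""


class IntervalError(MoodHRVError, ValueError):
    """Overlapping, inverted or out-of-range time intervals."""


class EmptyInputError(MoodHRVError, ValueError):
    """An operation received an empty stream or sample."""


class InsufficientDataError(MoodHRVError, ValueError):
    """Too few data points for the statistic to be defined."""


class NoNightError(MoodHRVError, ValueError):
    """The recording ends before the first full night window begins."""


class NoValidWindowError(MoodHRVError, ValueError):
    """Every sliding window of a night failed quality control."""


class ZeroVarianceError(MoodHRVError, ValueError):
    """Standardization requested on a constant sample."""


class SchemaError(MoodHRVError, ValueError):
    """A table or flag set does not match the expected schema."""


class LinkageError(MoodHRVError, ValueError):
    """An assessment could not be linked to its night HRV record."""


class ModelStructureError(MoodHRVError, ValueError):
    """Model variant incompatible with the data or parameter shapes."""


class ComparabilityError(MoodHRVError, ValueError):
    """Model comparison requested across different observation sets."""
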