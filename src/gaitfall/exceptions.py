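"""Exception hierarchy for the gait pipeline.

Every error raised on purpose by this package derives from :class:`GaitError`
so callers can catch pipeline failures without masking programming errors.
"""


class GaitError(Exception):
    """Base class for all gaitfall errors."""


class SchemaError(GaitError):
    """Input does not conform to the expected keypoint or table schema."""


class EmptyInputError(GaitError):
    """A file or sequence contained no usable data."""


class EmptySignalError(GaitError):
    """A trajectory has no valid samples to build a signal from."""


class SignalLengthError(GaitError):
    """Signal too short for the requested operation (e.g. smoothing window)."""


class ParameterError(GaitError):
    """Invalid parameter value (even smoothing window, bad fractions, ...)."""


class InsufficientEventsError(GaitError):
    """Too few detected gait events for the requested computation."""


class EventOrderingError(GaitError):
    """Gait events violate their required temporal ordering."""


class PairingError(GaitError):
    """No valid partner event found (e.g. no opposite toe-off after a heel strike)."""


class FeatureExtractionError(GaitError):
    """A gait feature could not be computed from the surviving events."""


class MappingError(GaitError):
    """External feature table is missing mandatory columns."""


class RegistryError(GaitError):
    """Unknown model name requested from the classifier registry."""
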