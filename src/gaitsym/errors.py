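"""Exception hierarchy shared by all pipeline stages."""


class GaitsymError(Exception):
    """Base class for all package errors."""


class FormatError(GaitsymError):
    """Marker file malformed or declares unknown units."""


class MissingMarkerError(FormatError):
    """A required foot marker is absent from the file."""


class GapTooLongError(GaitsymError):
    """A marker occlusion exceeds the interpolation limit."""


class FilterLengthError(GaitsymError):
    """Series too short for the requested zero-phase filter."""


class DerivativeLengthError(GaitsymError):
    """Series too short for finite differencing."""


class InsufficientEventsError(GaitsymError):
    """Fewer than two heel contacts detected on a foot."""


class NoStepsError(GaitsymError):
    """No valid alternating step interval could be assembled."""


class SideMissingError(GaitsymError):
    """A subject has no valid records on one side; SI undefined."""


class SIUndefinedError(GaitsymError):
    """Symmetry index undefined because both sides are zero."""


class ResponseCodingError(GaitsymError):
    """GHQ-12 response vector malformed (item count or codes)."""


class DegenerateInputError(GaitsymError):
    """Statistical input degenerate (zero variance, group too small)."""


class CollinearityError(GaitsymError):
    """Regression design matrix is rank deficient."""


class SpecError(GaitsymError):
    """Synthetic generator specification violates its invariants."""


class PipelineConfigError(GaitsymError):
    """Pipeline configuration invalid."""
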