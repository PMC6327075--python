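"""Exception hierarchy for the tracking pipeline."""


class VesicleTrackError(Exception):
    """Base class for all package errors."""


class FormatError(VesicleTrackError):
    """Input file or array does not match the expected format."""


class ParameterError(VesicleTrackError, ValueError):
    """A configuration parameter violates its contract."""


class DegenerateInputError(VesicleTrackError):
    """Input carries no usable signal (e.g. a constant response image)."""


class ContractViolationError(VesicleTrackError):
    """An internal data contract was violated by the caller."""


class SequencingError(VesicleTrackError):
    """Frames were processed out of order."""


class IntegrityError(VesicleTrackError):
    """Stored indices do not resolve against the detection data."""


class GenerationError(VesicleTrackError):
    """A synthetic script could not be generated under the given constraints."""


class UndefinedVelocityError(VesicleTrackError):
    """Velocity requested for a trajectory with fewer than two samples."""
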