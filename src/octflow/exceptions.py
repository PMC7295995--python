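"""Exception hierarchy shared across the framework."""


class OctflowError(Exception):
    """Base class for all framework errors."""


class InvalidGridError(OctflowError, ValueError):
    """Velocity grid bounds or size are invalid."""


class CoverageError(OctflowError, ValueError):
    """Scatterer strip too short to cover the beam during the acquisition."""


class NormalizationError(OctflowError, ValueError):
    """Record cannot be self-normalized (zero mean intensity)."""


class IncompleteBankError(OctflowError, ValueError):
    """Library does not cover every configured SNR level."""


class ConfigurationError(OctflowError, ValueError):
    """Scan and network/bank configurations are inconsistent."""


class EmptyMaskError(OctflowError, ValueError):
    """No pixels satisfy the vessel-mask criterion."""


class MissingPhaseError(OctflowError, ValueError):
    """Operation requires complex-valued data but only intensity is present."""


class RejectedAngleError(OctflowError, ValueError):
    """Doppler angle falls inside the unreliable near-perpendicular window."""


class InsufficientDataError(OctflowError, ValueError):
    """Too few pixels inside the masking aperture for a stable fit."""


class AllCorruptedError(OctflowError, ValueError):
    """Every phase-difference image was rejected as corrupted."""


class SchemaError(OctflowError, ValueError):
    """HDF5 container is missing required datasets or attributes."""


class CalibrationError(OctflowError, ValueError):
    """Calibration misuse (e.g. applying the scale factor twice)."""
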