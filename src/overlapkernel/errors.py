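"""Exception hierarchy used across the package."""


class OverlapKernelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OverlapKernelError):
    """A requested geometry / parameter combination is not realizable."""


class CalibrationError(OverlapKernelError):
    """Overlap region or calibration matrix cannot be formed or used."""


class AlignmentError(OverlapKernelError):
    """Pairwise phase maps do not form a connected chain over shots."""


class DimensionError(OverlapKernelError):
    """Array shapes of jointly used objects disagree."""
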