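"""Exception hierarchy.

Exit-code mapping used by the CLI: ``DataError`` subclasses exit 1,
``ConfigurationError`` exits 2.
"""


class GlyEcgError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlyEcgError):
    """Invalid or inconsistent pipeline configuration."""


class DataError(GlyEcgError):
    """Invalid input data."""


class UnsupportedFormatError(DataError):
    """Signal file format this build cannot read."""


class UnsupportedSamplingRateError(DataError):
    """ECG sampling rate differs from the configured rate (no resampling)."""


class CalibrationError(GlyEcgError):
    """Generator targets are mutually inconsistent."""


class GenerationError(GlyEcgError):
    """Synthetic cohort cannot satisfy the requested class counts."""


class SplitError(DataError):
    """Not enough labeled strips to form the train/validation split."""


class TrainingError(GlyEcgError):
    """Subject model cannot be fitted."""


class PredictionError(GlyEcgError):
    """Feature matrix incompatible with a fitted model."""


class MetricsError(GlyEcgError):
    """Performance metrics undefined for the given inputs."""


class DelineationError(GlyEcgError):
    """Fiducial points could not be located in a beat."""
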