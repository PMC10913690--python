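"""Exception hierarchy.

Each error class carries the process exit code the CLI maps it to:
2 configuration, 3 data/format, 4 insufficient signal or overlap.
"""


class HemophaseError(Exception):
    exit_code = 1


class ConfigError(HemophaseError):
    """Invalid configuration value or unsupported option combination."""

    exit_code = 2


class SingularMatrixError(ConfigError):
    """Extinction matrix is (numerically) singular for the chosen wavelength pair."""


class FormatError(HemophaseError):
    """Malformed or invalid input data."""

    exit_code = 3


class SamplingError(FormatError):
    """Timestamps deviate from the expected uniform grid."""


class DomainError(FormatError):
    """Value outside the mathematical domain of an operation."""


class InsufficientSignalError(HemophaseError):
    """Too few detected beats / windows to proceed."""

    exit_code = 4


class InsufficientDataError(InsufficientSignalError):
    """Too few data points for averaging, fitting or evaluation."""
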