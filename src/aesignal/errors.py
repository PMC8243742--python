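"""Exception hierarchy shared across the package.

Configuration problems (bad column mappings, invalid reference ranges,
malformed scenario files) and data problems (duplicate measurements,
insufficient or degenerate samples) are kept distinct so the command-line
layer can map them onto different exit codes.
"""


class AESignalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AESignalError):
    """User-supplied configuration is invalid (CLI exit code 2)."""


class DataError(AESignalError):
    """Input data violates a structural requirement (CLI exit code 3)."""


class InsufficientDataError(DataError):
    """Too few non-missing observations to compute the requested quantity."""


class DegenerateDistributionError(DataError):
    """A zero-variance sample was passed to a distributional method.

    Distributional proportions are undefined when the fitted spread is
    zero; callers must handle this explicitly rather than receive a
    proportion of exactly 0 or 1.
    """
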