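"""Exception hierarchy.

All package errors derive from :class:`MhsegError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class MhsegError(Exception):
    """Base class for all package errors."""


class ValidationError(MhsegError, ValueError):
    """Input violates a documented precondition or invariant."""


class NoEdgeError(MhsegError):
    """A scanline contains no intensity transition to fit."""


class FitFailureError(MhsegError):
    """The edge-profile least-squares fit did not converge."""


class InsufficientModesError(MhsegError):
    """The smoothed histogram has too few peaks for valley thresholding."""


class DegenerateHistogramError(MhsegError):
    """Too few occupied bins to place the requested number of thresholds."""


class NoRetinaError(MhsegError):
    """No retinal band could be traced (too many empty columns)."""


class FoveaNotFoundError(MhsegError):
    """No valid band columns in the central half of the scan."""


class NoInformativeFeaturesError(MhsegError):
    """Every feature column has zero variance."""
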