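"""Exception and warning hierarchy.

Exit-code mapping in the CLI: usage errors (click) -> 2,
:class:`DataValidationError` -> 3, :class:`NumericalError` and subclasses -> 4.
"""


class ResokError(Exception):
    """Base class for all package errors."""


class DataValidationError(ResokError):
    """Malformed input data: shapes, missing values, duplicate locations, bad columns."""


class SampleSizeError(DataValidationError):
    """Training size violates the n > 2p + 20 minimum for hybrid models."""


class NumericalError(ResokError):
    """Numerical failure: singular systems, degenerate fits, invalid variances."""


class KrigingError(NumericalError):
    """Singular or otherwise unsolvable kriging system."""


class VariogramFitError(NumericalError):
    """Spherical variogram fit failed or the empirical variogram is degenerate."""


class ConvergenceError(NumericalError):
    """Iterative solver did not converge within its iteration budget.

    Carries the last iterate so callers can inspect how far the solver got.
    """

    def __init__(self, message, last_iterate=None, last_change=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.last_change = last_change


class SmallSampleWarning(UserWarning):
    """Emitted when the n > 2p + 20 guard is overridden."""
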