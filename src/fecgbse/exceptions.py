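"""Exception hierarchy for fecgbse.

All package errors derive from :class:`FecgbseError` so callers can catch
one base class; the subclasses distinguish bad parameters, malformed files,
shape mismatches, and numerically degenerate situations.
"""


class FecgbseError(Exception):
    """Base class for all fecgbse errors."""


class ParameterError(FecgbseError, ValueError):
    """A scalar argument is out of its documented range."""


class ShapeError(FecgbseError, ValueError):
    """Array dimensions do not conform."""


class FormatError(FecgbseError, ValueError):
    """A signal file is malformed (ragged rows, non-numeric cells, empty)."""


class NumericError(FecgbseError, ArithmeticError):
    """Non-finite values encountered where finite data is required."""


class DegenerateDataError(FecgbseError, ValueError):
    """Input data carries no usable information (zero variance, all-zero)."""


class DegenerateUpdateError(FecgbseError, ArithmeticError):
    """A fixed-point update collapsed to (numerically) zero; restart with a
    different initial vector."""


class DivergenceError(FecgbseError, ArithmeticError):
    """An iterate became non-finite; reports the iteration at which it did."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"iterate became non-finite at iteration {iteration}")


class StageFailureError(FecgbseError, RuntimeError):
    """A stage of the two-stage pipeline failed to converge (abort policy)."""


class UndefinedBasinError(FecgbseError, ZeroDivisionError):
    """Basin-of-attraction condition is undefined for zero reference kurtosis."""
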