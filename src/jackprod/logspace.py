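"""Log-domain arithmetic for nonnegative magnitudes.

The application's convolution weights are configuration counts spanning
thousands of orders of magnitude (up to ~10^2608 for the largest circRNA),
far outside double range, so all heavy arithmetic stores magnitudes by
their natural logarithm.  A :class:`LogWeight` represents exactly the set
{0} ∪ (0, ∞): zero carries an explicit flag rather than a −inf sentinel so
the add/multiply paths stay branch-simple and portable.

Only (+, ×) are provided.  Subtraction is deliberately absent — the
convolution semigroup never needs it, and omitting it removes catastrophic
cancellation as a failure mode.  Base-10 logs appear only at reporting
boundaries (p-values too small for doubles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

__all__ = ["LogWeight", "lw_mul", "lw_add", "lw_sum", "lw_ratio_log10"]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class LogWeight:
    """A nonnegative magnitude stored as its natural log (or an exact zero)."""

    is_zero: bool
    log_value: float = 0.0  # meaningful only when is_zero is False

    @staticmethod
    def zero() -> "LogWeight":
        return LogWeight(True)

    @staticmethod
    def one() -> "LogWeight":
        return LogWeight(False, 0.0)

    @staticmethod
    def from_linear(x: float) -> "LogWeight":
        if x < 0:
            raise ValueError(f"LogWeight represents nonnegative magnitudes, got {x}")
        if x == 0:
            return LogWeight(True)
        return LogWeight(False, math.log(x))

    @staticmethod
    def from_log(log_value: float) -> "LogWeight":
        if math.isnan(log_value):
            raise ValueError("log value must not be NaN")
        if log_value == -math.inf:
            return LogWeight(True)
        return LogWeight(False, float(log_value))

    def to_linear(self) -> float:
        """Linear-scale value; overflows to inf / underflows to 0 outside double range."""
        if self.is_zero:
            return 0.0
        try:
            return math.exp(self.log_value)
        except OverflowError:
            return math.inf

    def log10(self) -> float:
        """log10 of the magnitude; −inf for zero."""
        return -math.inf if self.is_zero else self.log_value / _LN10


def lw_mul(a: LogWeight, b: LogWeight) -> LogWeight:
    if a.is_zero or b.is_zero:
        return LogWeight(True)
    return LogWeight(False, a.log_value + b.log_value)


def lw_add(a: LogWeight, b: LogWeight) -> LogWeight:
    """a + b by max-shifted log-sum-exp; exact when one side is zero."""
    if a.is_zero:
        return b
    if b.is_zero:
        return a
    m = max(a.log_value, b.log_value)
    return LogWeight(
        False, m + math.log(math.exp(a.log_value - m) + math.exp(b.log_value - m))
    )


def lw_sum(xs: Iterable[LogWeight]) -> LogWeight:
    """Sum a collection with a single global max shift (reproducible order)."""
    logs = [x.log_value for x in xs if not x.is_zero]
    if not logs:
        return LogWeight(True)
    m = max(logs)
    return LogWeight(False, m + math.log(math.fsum(math.exp(v - m) for v in logs)))


def lw_ratio_log10(num: LogWeight, den: LogWeight) -> float:
    """log10(num/den); −inf when num is zero.  Zero denominator is an error."""
    if den.is_zero:
        raise ZeroDivisionError("lw_ratio_log10: zero denominator")
    if num.is_zero:
        return -math.inf
    return (num.log_value - den.log_value) / _LN10
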