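"""Small shared helpers (rounding conventions used in reports)."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (report convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sigfig(x: float, sigfigs: int = 1) -> float:
    """Round ``x`` to ``sigfigs`` significant figures (half-up)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, ndigits=sigfigs - 1 - exponent)


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100*numerator/denominator rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty group is undefined")
    return round_half_up(100.0 * numerator / denominator, ndigits)
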