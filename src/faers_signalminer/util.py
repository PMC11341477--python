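"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as published signal tables do.

    Python's builtin ``round`` uses banker's rounding (2.675 -> 2.67);
    regulatory-style tables round half up (2.675 -> 2.68).  NaN passes
    through so undefined estimates stay undefined.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    quantum = Decimal(1).scaleb(-ndigits)
    # repr() gives the shortest decimal string, avoiding binary-float
    # artifacts like 2.675 -> 2.67499999...
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 2) -> float:
    """``count`` as a percentage of ``total``, rounded half-up."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, ndigits)
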