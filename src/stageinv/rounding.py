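"""Rounding used for reported values: half away from zero at fixed precision.

Binary floating-point `round` rounds half to even (0.965 -> 0.96); clinical
tables conventionally round half up, which is what reproduces e.g. a
c-statistic of 0.97 from (0.99 + 0.94) / 2.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
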