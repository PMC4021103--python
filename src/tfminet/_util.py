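"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero toward +inf (half-up).

    This is the single rounding rule used across the package for
    fractional counts and printed percentages (Python's built-in
    ``round`` is banker's rounding, which would print 92.85 -> 92.8
    or 92.9 depending on the binary representation).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up_int(x: float) -> int:
    return int(round_half_up(x, 0))
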