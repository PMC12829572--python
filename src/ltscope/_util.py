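"""Small shared helpers: rounding and percentage conventions."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Python's built-in ``round`` is banker's rounding; cohort percentages
    are reported with the conventional half-away-from-zero rule instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float | None:
    """100 * numerator / denominator rounded half-away-from-zero.

    Returns None (an undefined marker, never 0) when the denominator is zero.
    """
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, ndigits)
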