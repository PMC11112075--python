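"""Half-up decimal rounding and the "1:N" incidence formatting convention.

All published figures use round-half-up at the final step only (e.g. a
denominator of 103,488.5 prints as 1:103,489 and 2.6949% prints as 2.69%),
so ordinary banker's rounding is deliberately avoided here.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent", "format_one_in_n"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 × numerator/denominator, rounded half-up to ``ndigits`` decimals."""
    return round_half_up(100.0 * numerator / denominator, ndigits)


def format_one_in_n(denominator: int) -> str:
    """Format an incidence denominator as ``"1:3,000"``."""
    return f"1:{denominator:,d}"
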