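"""Centralized percentage/rounding conventions for printed tables.

Percentages are rendered with one decimal, rounding half away from zero,
matching the conventions of the comparison tables this package reproduces.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

__all__ = ["round_half_away", "agreement_pct"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (2.75 → 2.8, -2.75 → -2.8)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def agreement_pct(numerator: int, denominator: int, ndigits: int = 1) -> Optional[float]:
    """Percentage ``100 * numerator / denominator`` at table precision.

    Returns ``None`` (absent) when the denominator is zero — an undefined
    ratio is never reported as 0%.
    """
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, ndigits)
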