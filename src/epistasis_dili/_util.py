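"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention printed tables use), avoiding
    binary-float round-half-even surprises like round(66.35, 1) == 66.3."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(x: float, ndigits: int = 1) -> str:
    """Format a proportion as a percentage, half-up at ``ndigits``."""
    return f"{round_half_up(100 * x, ndigits):.{ndigits}f}%"
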