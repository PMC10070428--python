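"""Shared numeric/formatting helpers.

All reported percentages and means in this package are rounded half away
from zero to one decimal, so that e.g. 642/797 prints as 80.6%.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round1(x: float) -> float:
    """Round to one decimal, ties away from zero (not banker's rounding)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float) -> float:
    """Percentage of ``numerator`` over ``denominator``, one decimal."""
    if denominator == 0:
        raise ValueError("percentage denominator is zero")
    return round1(100.0 * numerator / denominator)


def fmt_mean_sd_range(mean: float, sd: float | None, lo: float, hi: float) -> str:
    """Format a summary as ``'9.9 ± 4.9 (range 0–34)'``.

    ``sd=None`` (single observation) renders as ``NA``.
    """
    sd_str = "NA" if sd is None else f"{round1(sd):.1f}"
    lo_s = f"{int(lo)}" if float(lo).is_integer() else f"{round1(lo):.1f}"
    hi_s = f"{int(hi)}" if float(hi).is_integer() else f"{round1(hi):.1f}"
    return f"{round1(mean):.1f} ± {sd_str} (range {lo_s}–{hi_s})"
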