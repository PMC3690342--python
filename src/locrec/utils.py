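"""Shared small utilities: percentage rounding and formatting.

Every percentage the package emits goes through :func:`round_pct`, which
rounds half away from zero (62.5 -> 63). This is the convention that
reproduces the reference corpus's printed agreement percentages from its
raw counts; Python's built-in banker's rounding would not.
"""

from __future__ import annotations

import math


def round_pct(x: float) -> int:
    """Round a non-negative percentage to the nearest integer, half away
    from zero.

    >>> round_pct(84.65)
    85
    >>> round_pct(62.5)
    63
    """
    if x < 0:
        raise ValueError(f"percentage must be non-negative, got {x}")
    return int(math.floor(x + 0.5))


def pct_or_none(numerator: int, denominator: int) -> int | None:
    """``round_pct(100 * numerator / denominator)``, or None when the
    denominator is zero (undefined, not 0)."""
    if denominator == 0:
        return None
    return round_pct(100.0 * numerator / denominator)


def fmt_pct(value: int | None) -> str:
    """Render an integer percent for TSV output; undefined -> ``NA``."""
    return "NA" if value is None else str(value)
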