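"""Shared numeric formatting helpers.

Every "matches the printed value" comparison in reports and tests goes
through :func:`round_half_away` so the rounding convention (half away
from zero, to the printed precision) lives in exactly one place.
"""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero to ``ndigits`` decimal places."""
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1.0 if scaled >= 0 else -1.0)
    result = rounded / factor
    return result if ndigits > 0 else float(result)


def fmt(x: float, ndigits: int) -> str:
    """Format with the package rounding convention."""
    return f"{round_half_away(x, ndigits):.{ndigits}f}"
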