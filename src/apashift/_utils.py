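"""Small numeric helpers shared across modules."""
from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; the shift statistics
    round halves away from zero (e.g. 0.5 -> 1, -0.5 -> -1, 1.5 -> 2).
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def as_percent(numerator: float, denominator: float) -> int:
    """Integer percentage of numerator/denominator, halves away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator)
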