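"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention behind every
    reported percentage: 91.375 -> 91.38, not banker's 91.38/91.37 ambiguity)."""
    q = Decimal(10) ** -ndigits
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage a/b*100 rounded half-away-from-zero to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def check_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
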