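"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

MISSING = -1  # sentinel for a missing genotype call


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero at the given decimal place.

    Banker's rounding (Python's built-in) would turn 0.125 into 0.12; the
    frequency tables in this package use conventional half-up rounding so
    that printed percentages match hand calculation.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def star_sort_key(allele: str) -> tuple[int, str]:
    """Sort key for star-allele names: numeric part, then letter suffix.

    '*2' -> (2, ''), '*3C' -> (3, 'C').
    """
    body = allele.lstrip("*")
    i = 0
    while i < len(body) and body[i].isdigit():
        i += 1
    num = int(body[:i]) if i else 0
    return num, body[i:]
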