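"""Half-away-from-zero rounding on the shortest decimal repr of a float.

All reported quantities in this package round ties away from zero
(2105.5 -> 2106), not to even as Python's built-in ``round`` does. Using the
shortest round-tripping decimal representation avoids binary-float artefacts
such as 2.675 -> '2.67499...' mis-rounding at two decimals.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round *value* to *ndigits* decimals, ties away from zero.

    Returns an ``int`` when ``ndigits == 0`` so integer-kcal and integer-gram
    reports carry no spurious ``.0``.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    rounded = Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return int(rounded) if ndigits == 0 else float(rounded)
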