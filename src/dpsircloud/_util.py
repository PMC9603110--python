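from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Printed reference values in grade-assessment tables use commercial
    (half-up) rounding, not banker's rounding, so ``round()`` is not a
    faithful comparison helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
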