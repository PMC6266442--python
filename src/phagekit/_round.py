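"""Half-up decimal rounding, used for every reported percentage/mass/pH.

Python's builtin ``round`` is banker's rounding; tabulated values in the
field (GC%, codon-usage %, MW, pI, percent identity) are conventionally
rounded half-up, so all user-facing numbers go through :func:`round_half_up`.
"""

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places, ties away from zero.

    >>> round_half_up(2.5)
    3.0
    >>> round_half_up(99.405, 2)
    99.41
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
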