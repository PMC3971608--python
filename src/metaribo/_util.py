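"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
from collections.abc import Sequence


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (15.5 -> 16, -15.5 -> -16)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def largest_remainder(values: Sequence[float], total: int = 100) -> tuple[int, ...]:
    """Integerize proportions so they sum exactly to ``total``.

    Each value receives floor(share) seats; leftover seats go to the largest
    fractional remainders, ties resolved in favour of earlier entries.
    """
    s = float(sum(values))
    if s <= 0:
        raise ValueError("largest_remainder requires a positive total of values")
    shares = [total * v / s for v in values]
    floors = [int(math.floor(sh)) for sh in shares]
    leftover = total - sum(floors)
    # stable sort: ties keep input order, so earlier samples win ties
    order = sorted(range(len(values)), key=lambda i: -(shares[i] - floors[i]))
    out = list(floors)
    for i in order[:leftover]:
        out[i] += 1
    return tuple(out)
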