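"""Small shared helpers."""

from __future__ import annotations

import math


def round_report(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used on reported lengths.

    Python's built-in ``round`` is banker's rounding; clinical tables round
    2.45 -> 2.5, not 2.4.  A small epsilon guards against values like
    ``0.25000000000000006`` produced by binary floating point.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5 + 1e-9) / factor, x)


def quadrature(*sds: float) -> float:
    """Combine independent one-sigma uncertainties in quadrature.

    ``hypot`` rather than sqrt-of-sum-of-squares: immune to under/overflow.
    """
    return math.hypot(*sds)
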