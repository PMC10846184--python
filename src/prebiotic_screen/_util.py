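"""Numerical helpers shared by the screening stages."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_EVEN, Decimal

from .model_core import TOL_ZERO


def round6(x: float) -> float:
    """Round to six decimals, half to even, on the decimal representation."""
    if not math.isfinite(x):
        return x
    return float(Decimal(repr(float(x))).quantize(Decimal("1e-6"), ROUND_HALF_EVEN))


def relative_change(baseline: float, supplemented: float, tol_zero: float = TOL_ZERO) -> float:
    """(supplemented - baseline) / baseline on 6-decimal-rounded inputs.

    Both values are quantized to six decimals (half to even) before the ratio,
    and the ratio itself is computed in decimal arithmetic so that a change of
    exactly 0.01 compares as exactly 0.01 downstream.  A zero baseline yields
    +inf when the supplemented value is above ``tol_zero`` (de-novo growth, the
    strongest possible effect) and 0 otherwise.
    """
    b = Decimal(repr(float(baseline))).quantize(Decimal("1e-6"), ROUND_HALF_EVEN)
    s = Decimal(repr(float(supplemented))).quantize(Decimal("1e-6"), ROUND_HALF_EVEN)
    if b == 0:
        return math.inf if float(s) > tol_zero else 0.0
    return float((s - b) / b)
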