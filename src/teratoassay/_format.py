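"""Significant-figure rounding and the mantissa × 10^exponent rendering used in reports."""

from __future__ import annotations

import math
import re

_SCI_RE = re.compile(r"^\s*([0-9.]+)\s*(?:×|x)\s*10\^(-?\d+)\s*$")


def round_sig(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig - 1 - exponent)


def format_scientific(x: float, sig: int = 3) -> str:
    """Render ``x`` as e.g. ``"3.16 × 10^6"`` with a ``sig``-figure mantissa.

    Mantissas that round up to 10 roll over into the next exponent, so the
    mantissa always lies in [1, 10).
    """
    if x <= 0 or not math.isfinite(x):
        raise ValueError(f"cannot render non-positive value {x!r}")
    exponent = math.floor(math.log10(x))
    mantissa = round(x / 10**exponent, sig - 1)
    if mantissa >= 10.0:
        mantissa /= 10.0
        exponent += 1
    return f"{mantissa:.{sig - 1}f} × 10^{exponent}"


def parse_scientific(text: str) -> float:
    """Inverse of :func:`format_scientific` (also accepts plain floats)."""
    m = _SCI_RE.match(text)
    if m:
        return float(m.group(1)) * 10 ** int(m.group(2))
    return float(text)
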