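"""Unit conversions onto the internal mg / mL / cm / s system.

Ocular PK parameter tables mix five different time units (s, min, h for
rates; uL and mL for volumes; L/h for clearance).  Every quantity is
converted once, at scenario compilation, onto a single base system so the
ODE right-hand side never multiplies mismatched units.
"""

from __future__ import annotations

#: multiplicative factors, keyed "<from>-><to>"; internal unit is the target
FACTORS: dict[str, float] = {
    "uL->mL": 1e-3,
    "uL/min->mL/s": 1e-3 / 60.0,
    "1/min->1/s": 1.0 / 60.0,
    "1/h->1/s": 1.0 / 3600.0,
    "L/h->mL/s": 1e3 / 3600.0,
    "L->mL": 1e3,
    "h->s": 3600.0,
    "min->s": 60.0,
    "um->cm": 1e-4,
    "g/mL->mg/mL": 1e3,
    "percent->fraction": 1e-2,
}


def to_internal(value: float, conversion: str) -> float:
    """Convert ``value`` along a named conversion (e.g. ``"uL/min->mL/s"``)."""
    try:
        return value * FACTORS[conversion]
    except KeyError:
        raise ValueError(f"unit conversion not recognized: {conversion!r}") from None


def from_internal(value: float, conversion: str) -> float:
    """Inverse of :func:`to_internal` for the same conversion key."""
    try:
        return value / FACTORS[conversion]
    except KeyError:
        raise ValueError(f"unit conversion not recognized: {conversion!r}") from None
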