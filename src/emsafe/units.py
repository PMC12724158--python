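"""Unit normalization for the small set of dimensions the ontology uses.

Thresholds mix mg/kg doses and minutes, so every quantity is converted to
its node's declared unit before any comparison; cross-dimension conversions
raise rather than silently passing numbers through.
"""
from __future__ import annotations

__all__ = ["UnitError", "convert"]


class UnitError(ValueError):
    pass


# Factors to a per-dimension base unit (mg, kg, min).
_DIMENSIONS: tuple[dict[str, float], ...] = (
    {  # drug mass, base mg
        "mg": 1.0, "milligram": 1.0, "milligrams": 1.0,
        "mcg": 1e-3, "ug": 1e-3, "microgram": 1e-3, "micrograms": 1e-3,
        "g": 1e3, "gram": 1e3, "grams": 1e3,
    },
    {  # body mass, base kg
        "kg": 1.0, "kilogram": 1.0, "kilograms": 1.0,
        "lb": 0.45359237, "lbs": 0.45359237,
    },
    {  # elapsed time, base min
        "min": 1.0, "mins": 1.0, "minute": 1.0, "minutes": 1.0,
        "s": 1 / 60, "sec": 1 / 60, "secs": 1 / 60, "second": 1 / 60, "seconds": 1 / 60,
        "h": 60.0, "hr": 60.0, "hrs": 60.0, "hour": 60.0, "hours": 60.0,
    },
)


def convert(value: float, src_unit: str, dst_unit: str) -> float:
    """Convert ``value`` from ``src_unit`` to ``dst_unit`` within one dimension."""
    src, dst = src_unit.strip().lower(), dst_unit.strip().lower()
    if src == dst:
        return float(value)
    for table in _DIMENSIONS:
        if dst in table:
            if src not in table:
                raise UnitError(f"cannot convert {src_unit!r} to {dst_unit!r}: different dimensions")
            return float(value) * table[src] / table[dst]
    raise UnitError(f"unknown unit {dst_unit!r}")
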