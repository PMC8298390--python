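"""Minimal unit handling.

Everything internal is SI (molar, seconds, metres, litres). Public
interfaces accept either a plain float already in the internal unit or a
string with an explicit tag, e.g. ``"400 nM"``, ``"60 pL"``, ``"10 um"``.
"""

from __future__ import annotations

import re

from .errors import ValidationError

# multiplicative factors to the internal unit
_CONCENTRATION = {  # -> molar
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "nM": 1e-9,
    "pM": 1e-12,
}
_VOLUME = {  # -> litre
    "L": 1.0,
    "mL": 1e-3,
    "uL": 1e-6,
    "µL": 1e-6,
    "nL": 1e-9,
    "pL": 1e-12,
    "fL": 1e-15,
}
_LENGTH = {  # -> metre
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
}
_TIME = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6, "min": 60.0, "h": 3600.0}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]+)\s*$")


def _convert(value, table: dict, kind: str) -> float:
    if isinstance(value, str):
        m = _QTY_RE.match(value)
        if m is None:
            raise ValidationError(f"cannot parse {kind} quantity {value!r}")
        number, unit = m.groups()
        if unit not in table:
            raise ValidationError(
                f"unknown {kind} unit {unit!r}; accepted: {sorted(table)}"
            )
        return float(number) * table[unit]
    return float(value)


def molar(value) -> float:
    """Concentration in molar; strings like ``'90 uM'`` are converted."""
    return _convert(value, _CONCENTRATION, "concentration")


def litres(value) -> float:
    """Volume in litres; strings like ``'60 pL'`` are converted."""
    return _convert(value, _VOLUME, "volume")


def metres(value) -> float:
    """Length in metres; strings like ``'10 um'`` are converted."""
    return _convert(value, _LENGTH, "length")


def seconds(value) -> float:
    """Time in seconds; strings like ``'10 ms'`` are converted."""
    return _convert(value, _TIME, "time")


def require_positive(**kwargs) -> None:
    """Raise :class:`ValidationError` naming the first non-positive argument."""
    for name, value in kwargs.items():
        if not value > 0:
            raise ValidationError(f"{name} must be strictly positive, got {value}")


def require_non_negative(**kwargs) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValidationError(f"{name} must be non-negative, got {value}")
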