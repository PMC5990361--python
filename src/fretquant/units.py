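"""Minimal concentration-unit handling.

Concentrations travel through the package as plain floats tagged with a unit
string; this module centralises validation and conversion to a common scale
(micromolar) so that calibration constants and data axes can be compared.
"""

from __future__ import annotations

_TO_UM = {
    "pM": 1e-6,
    "nM": 1e-3,
    "uM": 1.0,
    "µM": 1.0,
    "mM": 1e3,
    "M": 1e6,
}


def to_micromolar(value, unit: str):
    """Convert ``value`` expressed in ``unit`` to micromolar."""
    try:
        factor = _TO_UM[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_TO_UM)}"
        ) from None
    return value * factor


def convert(value, from_unit: str, to_unit: str):
    """Convert between any two supported concentration units."""
    if to_unit not in _TO_UM:
        raise ValueError(f"unknown concentration unit {to_unit!r}")
    return to_micromolar(value, from_unit) / _TO_UM[to_unit]
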