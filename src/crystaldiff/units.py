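"""Unit conversions between the user-facing scales (µm, min) and SI (m, s).

All public quantities follow one convention: lengths at the user surface are
micrometres, times are minutes, and diffusion coefficients are always SI
(m²/s).  Every conversion in the package goes through this module so that a
unit error can only be made in one place.
"""

from __future__ import annotations

M_PER_UM: float = 1e-6
S_PER_MIN: float = 60.0

_LENGTH_TO_M = {"m": 1.0, "um": M_PER_UM, "µm": M_PER_UM, "nm": 1e-9}
_TIME_TO_S = {"s": 1.0, "min": S_PER_MIN, "h": 3600.0}


def um_to_m(value: float) -> float:
    return value * M_PER_UM


def m_to_um(value: float) -> float:
    return value / M_PER_UM


def min_to_s(value: float) -> float:
    return value * S_PER_MIN


def s_to_min(value: float) -> float:
    return value / S_PER_MIN


def um2_to_m2(value: float) -> float:
    return value * M_PER_UM**2


def m2_to_um2(value: float) -> float:
    return value / M_PER_UM**2


def length_to_m(value: float, unit: str) -> float:
    """Convert a length in ``unit`` ∈ {m, um, µm, nm} to metres."""
    try:
        return value * _LENGTH_TO_M[unit]
    except KeyError:
        raise ValueError(f"unknown length unit {unit!r}") from None


def time_to_s(value: float, unit: str) -> float:
    """Convert a time in ``unit`` ∈ {s, min, h} to seconds."""
    try:
        return value * _TIME_TO_S[unit]
    except KeyError:
        raise ValueError(f"unknown time unit {unit!r}") from None
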