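"""Monthly daylength from solar-declination geometry.

Mid-month day-of-year, declination from the standard sinusoidal
approximation, sunset hour angle clamped for polar day/night. A 365-day
calendar is used throughout (monthly climatology; leap days are ignored).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MID_MONTH_DOY", "DAYS_IN_MONTH", "solar_declination", "monthly_daylength"]

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])

_OBLIQUITY = 23.44  # degrees


def solar_declination(doy) -> np.ndarray:
    """Solar declination (degrees) at day-of-year ``doy`` (1..365)."""
    doy = np.asarray(doy, dtype=float)
    return _OBLIQUITY * np.sin(2.0 * np.pi * (doy - 81.0) / 365.0)


def monthly_daylength(latitude: float) -> np.ndarray:
    """Mean daylength (hours) for each of the 12 months at ``latitude`` (deg N).

    Evaluated at mid-month day-of-year. Poleward of the polar circle the
    sunset hour angle is clamped, giving 0 h (polar night) or 24 h
    (polar day).
    """
    phi = np.radians(latitude)
    delta = np.radians(solar_declination(MID_MONTH_DOY))
    cos_omega = -np.tan(phi) * np.tan(delta)
    cos_omega = np.clip(cos_omega, -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return 24.0 * omega / np.pi
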