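"""Daily solar geometry: declination, daylength, daytime-mean zenith angle,
extraterrestrial radiation, and the diurnal shape used for daylight
integration.

All functions are vectorized over latitude. The model runs on a 365-day
calendar; day-of-year is 1-based.
"""

from __future__ import annotations

import numpy as np

from ecosink.units import DAYS_PER_YEAR

#: Solar constant, W m^-2.
SOLAR_CONSTANT = 1361.0

#: cos(theta) below which a day counts as polar night (no daylight).
POLAR_NIGHT_COS = 0.0


def declination(day_of_year) -> np.ndarray:
    """Solar declination, radians (Cooper's formula)."""
    doy = np.asarray(day_of_year, dtype=float)
    return np.deg2rad(-23.45) * np.cos(2.0 * np.pi * (doy + 10.0) / DAYS_PER_YEAR)


def sunset_hour_angle(lat_deg, day_of_year) -> np.ndarray:
    """Sunset hour angle omega_s in radians; 0 = polar night, pi = midnight sun."""
    phi = np.deg2rad(np.asarray(lat_deg, dtype=float))
    delta = declination(day_of_year)
    cos_ws = -np.tan(phi) * np.tan(delta)
    return np.arccos(np.clip(cos_ws, -1.0, 1.0))


def daylength_hours(lat_deg, day_of_year) -> np.ndarray:
    """Daylight duration in hours (0 during polar night, 24 under midnight sun)."""
    return 24.0 / np.pi * sunset_hour_angle(lat_deg, day_of_year)


def daily_mean_cos_zenith(lat_deg, day_of_year) -> np.ndarray:
    """Daytime mean of cos(zenith): the integral of cos(theta) over daylight
    hours divided by the daylength. Returns 0 where there is no daylight."""
    phi = np.deg2rad(np.asarray(lat_deg, dtype=float))
    delta = declination(day_of_year)
    ws = sunset_hour_angle(lat_deg, day_of_year)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cos = (
            np.sin(phi) * np.sin(delta) * ws + np.cos(phi) * np.cos(delta) * np.sin(ws)
        ) / np.where(ws > 0, ws, np.nan)
    mean_cos = np.where(ws > 0, mean_cos, 0.0)
    return np.maximum(np.nan_to_num(mean_cos), 0.0)


def daily_solar_zenith(lat_deg, day_of_year):
    """Daily mean solar zenith angle, radians.

    The mean is cosine-weighted over daylight hours: cos(theta_mean) equals
    the daytime integral of cos(theta) divided by daylength. Polar night is
    flagged by theta = pi/2 together with zero daylength; downstream code
    treats that sentinel as zero photosynthesis.

    Returns
    -------
    theta : radians
    daylength : hours
    """
    if np.any(np.abs(np.asarray(lat_deg, dtype=float)) > 90.0):
        raise ValueError("latitude must lie in [-90, 90]")
    doy = np.asarray(day_of_year)
    if np.any(doy < 1) or np.any(doy > DAYS_PER_YEAR):
        raise ValueError("day_of_year must lie in [1, 365]")
    mean_cos = daily_mean_cos_zenith(lat_deg, day_of_year)
    theta = np.arccos(np.clip(mean_cos, 0.0, 1.0))
    return theta, daylength_hours(lat_deg, day_of_year)


def extraterrestrial_radiation(lat_deg, day_of_year) -> np.ndarray:
    """Daily top-of-atmosphere shortwave, MJ m^-2 d^-1 (used for the
    clearness index that splits direct from diffuse)."""
    phi = np.deg2rad(np.asarray(lat_deg, dtype=float))
    delta = declination(day_of_year)
    ws = sunset_hour_angle(lat_deg, day_of_year)
    ra = (
        86400.0
        / np.pi
        * SOLAR_CONSTANT
        * (np.sin(phi) * np.sin(delta) * ws + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return np.maximum(ra, 0.0) / 1.0e6


# 3-point Gauss-Legendre nodes/weights on [0, 1]
GAUSS_NODES = np.array([0.5 - np.sqrt(0.15), 0.5, 0.5 + np.sqrt(0.15)])
GAUSS_WEIGHTS = np.array([5.0 / 18.0, 8.0 / 18.0, 5.0 / 18.0])


def diurnal_cos_zenith(lat_deg, day_of_year, frac_of_daylight) -> np.ndarray:
    """cos(zenith) at a fractional position of the daylight period
    (0 = sunrise, 0.5 = solar noon, 1 = sunset)."""
    phi = np.deg2rad(np.asarray(lat_deg, dtype=float))
    delta = declination(day_of_year)
    ws = sunset_hour_angle(lat_deg, day_of_year)
    # hour angle runs from -ws (sunrise) to +ws (sunset)
    w = (2.0 * np.asarray(frac_of_daylight, dtype=float) - 1.0) * ws
    cz = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(w)
    return np.maximum(cz, 0.0)


def diurnal_shortwave(srad_daily_mj, lat_deg, day_of_year, frac_of_daylight):
    """Instantaneous shortwave (W m^-2) at a fractional daylight position,
    distributing the daily total proportionally to cos(zenith).

    The integral of the returned flux over the daylight period recovers the
    daily total exactly (up to quadrature error).
    """
    mean_cos = daily_mean_cos_zenith(lat_deg, day_of_year)
    dl_s = daylength_hours(lat_deg, day_of_year) * 3600.0
    cz = diurnal_cos_zenith(lat_deg, day_of_year, frac_of_daylight)
    with np.errstate(invalid="ignore", divide="ignore"):
        sw = np.asarray(srad_daily_mj, dtype=float) * 1.0e6 / dl_s * cz / mean_cos
    return np.nan_to_num(sw, nan=0.0, posinf=0.0)
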