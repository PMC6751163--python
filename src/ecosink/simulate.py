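"""Daily integration of the pool model over a forcing period.

``run_period`` advances an :class:`~ecosink.pools.EcosystemState` through a
span of years of a :class:`~ecosink.forcing.ForcingSet`, aggregating the
daily fluxes to annual per-pixel sums (g C m-2 yr-1). Overrides allow the
spin-up and scenario machinery to repeat a single climate year, pin LAI to
a climatology, or fix CO2 / N deposition.
"""

from __future__ import annotations

import numpy as np

from ecosink.forcing import ForcingSet, LaiSeries, composite_to_daily
from ecosink.params import ParamSet
from ecosink.pools import EcosystemState, pft_vcmax_scale, step_day
from ecosink.units import DAYS_PER_YEAR

ANNUAL_FLUXES = ("gpp", "npp", "ar", "hr", "nep")


def daily_lai_climatology(forcing: ForcingSet, window: tuple[int, int]) -> np.ndarray:
    """Daily (365, n_pix) LAI climatology: composite-date mean over a year
    window, interpolated to days (seasonality preserved)."""
    sel = (forcing.years >= window[0]) & (forcing.years <= window[1])
    if not np.any(sel):
        raise ValueError(f"window {window} not covered by forcing")
    clim_comp = forcing.lai.values[sel].mean(axis=0, dtype=np.float64)
    one = LaiSeries(values=clim_comp[None].astype(np.float32),
                    composite_doys=forcing.lai.composite_doys,
                    composite_length=forcing.lai.composite_length)
    return composite_to_daily(one)[0]


def seasonal_drop(daily_clim: np.ndarray) -> np.ndarray:
    """Expected relative day-over-day LAI drop (365, n_pix) from a daily
    climatology; wraps the year boundary."""
    prev = np.roll(daily_clim, 1, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        drop = np.where(prev > 1e-6, (prev - daily_clim) / np.maximum(prev, 1e-6), 0.0)
    return np.maximum(drop, 0.0)


def run_period(
    state: EcosystemState,
    forcing: ForcingSet,
    years: tuple[int, int],
    params: ParamSet,
    lai_daily_override: np.ndarray | None = None,
    met_year: int | None = None,
    co2_override: float | None = None,
    ndep_override: np.ndarray | None = None,
    clim_drop: np.ndarray | None = None,
    prev_lai: np.ndarray | None = None,
    budget: dict | None = None,
):
    """Integrate day by day over ``years`` (inclusive), mutating ``state``.

    Overrides:

    * ``lai_daily_override`` — (365, n_pix) daily LAI applied to every year
      (otherwise the forcing's composite LAI, interpolated);
    * ``met_year`` — repeat this calendar year's meteorology every year;
    * ``co2_override`` / ``ndep_override`` — fixed CO2 (p.p.m.) and annual
      N deposition (n_pix,) instead of the forcing's transient drivers;
    * ``clim_drop`` — (365, n_pix) expected seasonal relative LAI drop used
      by the disturbance trigger (default: no expected drop).

    Returns a dict of annual per-pixel flux sums, each (n_years, n_pix), in
    g C m-2 yr-1, for gpp, npp, ar, hr, nep.
    """
    y0, y1 = years
    year_list = list(range(y0, y1 + 1))
    n_pix = forcing.grid.n_pix
    out = {name: np.zeros((len(year_list), n_pix)) for name in ANNUAL_FLUXES}

    pscale = pft_vcmax_scale(forcing.static, params)
    if clim_drop is None:
        clim_drop = np.zeros((DAYS_PER_YEAR, n_pix))
    lai_all = None if lai_daily_override is not None else forcing.daily_lai()

    for iy, year in enumerate(year_list):
        yi = forcing.year_index(year)
        mi = yi if met_year is None else forcing.year_index(met_year)
        met = forcing.met
        tmax = np.asarray(met.tmax[mi], dtype=float)
        tmin = np.asarray(met.tmin[mi], dtype=float)
        srad = np.asarray(met.srad[mi], dtype=float)
        rh = np.asarray(met.rh[mi], dtype=float)
        precip = np.asarray(met.precip[mi], dtype=float)

        lai_year = (lai_daily_override if lai_daily_override is not None
                    else lai_all[yi])
        co2 = float(forcing.drivers.co2[yi]) if co2_override is None \
            else float(co2_override)
        ndep_y = (forcing.drivers.ndep[yi] if ndep_override is None
                  else ndep_override)
        ndep_daily = np.asarray(ndep_y, dtype=float) / DAYS_PER_YEAR

        if prev_lai is None:
            prev_lai = np.asarray(lai_year[0], dtype=float)
        for d in range(DAYS_PER_YEAR):
            lai_today = np.asarray(lai_year[d], dtype=float)
            day = {
                "doy": d + 1,
                "tmax": tmax[d], "tmin": tmin[d], "srad": srad[d],
                "rh": rh[d], "precip": precip[d],
                "lai_today": lai_today, "lai_yesterday": prev_lai,
                "clim_drop": clim_drop[d], "co2": co2,
                "ndep_daily": ndep_daily,
            }
            fx = step_day(state, day, forcing.static, params,
                          pft_scale=pscale, budget=budget)
            out["gpp"][iy] += fx.gpp
            out["npp"][iy] += fx.npp
            out["ar"][iy] += fx.ar_maintenance + fx.ar_growth
            out["hr"][iy] += fx.hr
            out["nep"][iy] += fx.nep
            prev_lai = lai_today
    return out
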