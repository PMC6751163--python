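"""Synthetic gridded forcing and baseline-scenario construction.

The generators emulate the statistical structure of the real inputs the
analysis assumes — daily meteorology with seasonality, AR(1) weather noise
and optional secular trends; composite-period LAI with seasonality, a
greening trend, and sampling noise; a rising global CO2 scalar; and gridded
nitrogen deposition that conserves a prescribed global total. They do not
attempt to reproduce any real satellite or reanalysis field.

``make_baseline`` builds the counterfactual forcing for the factorial
attribution experiment: drivers flagged ``baseline`` are frozen at their
period-start level (CO2, N deposition), replaced by a pre-period composite
climatology (LAI), or resampled from a pre-period window (climate).

All years have 365 days (no leap days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import lfilter

from ecosink.grid import GridSpec, PixelStatic
from ecosink.solar import extraterrestrial_radiation
from ecosink.units import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

MET_VARS = ("tmax", "tmin", "srad", "rh", "precip")
DRIVERS = ("lai", "co2", "ndep", "climate")


def year_array(years) -> np.ndarray:
    """Normalize a year specification (range, (start, end) tuple inclusive,
    or explicit sequence) to an int array."""
    if isinstance(years, tuple) and len(years) == 2:
        return np.arange(years[0], years[1] + 1)
    arr = np.asarray(list(years), dtype=int)
    if arr.size == 0:
        raise ValueError("year range is empty")
    return arr


@dataclass
class MetSeries:
    """Daily meteorology, arrays of shape (n_years, 365, n_pix)."""

    tmax: np.ndarray  # degC
    tmin: np.ndarray  # degC
    srad: np.ndarray  # MJ m-2 d-1
    rh: np.ndarray  # %
    precip: np.ndarray  # mm d-1

    def validate(self) -> None:
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax must be >= tmin everywhere")
        if np.any(self.rh < 0) or np.any(self.rh > 100):
            raise ValueError("relative humidity must lie in [0, 100]")
        if np.any(self.srad < 0):
            raise ValueError("srad must be non-negative")
        if np.any(self.precip < 0):
            raise ValueError("precip must be non-negative")

    def copy(self) -> "MetSeries":
        return MetSeries(**{v: getattr(self, v).copy() for v in MET_VARS})


@dataclass
class LaiSeries:
    """Composite-period LAI: values (n_years, n_composites, n_pix),
    composite day-of-year vector strictly increasing."""

    values: np.ndarray  # m2/m2
    composite_doys: np.ndarray  # 1-based day of year per composite
    composite_length: int  # days (8 or 16)

    def validate(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("LAI must be non-negative")
        if np.any(np.diff(self.composite_doys) <= 0):
            raise ValueError("composite dates must be strictly increasing")

    def copy(self) -> "LaiSeries":
        return LaiSeries(self.values.copy(), self.composite_doys.copy(),
                         self.composite_length)


@dataclass
class DriverRecord:
    """Annual drivers: global CO2 scalar (p.p.m.) and per-pixel nitrogen
    deposition (g N m-2 yr-1)."""

    co2: np.ndarray  # (n_years,)
    ndep: np.ndarray  # (n_years, n_pix)

    def validate(self) -> None:
        if np.any(self.co2 <= 0):
            raise ValueError("CO2 must be positive")
        if np.any(self.ndep < 0):
            raise ValueError("N deposition must be non-negative")


@dataclass
class ScenarioSpec:
    """One factorial experiment: per-driver mode and the baseline windows.

    ``modes`` maps each of ``lai, co2, ndep, climate`` to ``"transient"``
    (use the forcing as generated) or ``"baseline"`` (freeze / resample per
    the baseline rules). ``period`` is the simulated (start, end) years; if
    None the full forcing range is simulated.
    """

    modes: Mapping[str, str]
    baseline_lai_window: tuple[int, int] = (1982, 1986)
    climate_resample_window: tuple[int, int] = (1971, 1979)
    period: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(DRIVERS) - set(self.modes)
        if missing:
            raise ValueError(f"modes missing for drivers: {sorted(missing)}")
        bad = {d: m for d, m in self.modes.items() if m not in ("transient", "baseline")}
        if bad:
            raise ValueError(f"invalid modes: {bad}")

    def all_transient(self) -> bool:
        return all(self.modes[d] == "transient" for d in DRIVERS)


@dataclass
class ForcingSet:
    """Gridded forcing bundle: grid + static pixel attributes, daily
    meteorology, composite LAI, annual CO2 and N deposition."""

    grid: GridSpec
    static: PixelStatic
    years: np.ndarray
    met: MetSeries
    lai: LaiSeries
    drivers: DriverRecord
    _daily_lai_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not covered by forcing "
                           f"({self.years[0]}..{self.years[-1]})")
        return int(idx[0])

    def daily_lai(self) -> np.ndarray:
        """Daily LAI (n_years, 365, n_pix) interpolated from composites;
        cached after the first call."""
        if self._daily_lai_cache is None:
            self._daily_lai_cache = composite_to_daily(self.lai)
        return self._daily_lai_cache

    def copy(self) -> "ForcingSet":
        return ForcingSet(
            grid=self.grid,
            static=self.static,
            years=self.years.copy(),
            met=self.met.copy(),
            lai=self.lai.copy(),
            drivers=DriverRecord(self.drivers.co2.copy(), self.drivers.ndep.copy()),
        )


def _ar1(rng: np.random.Generator, shape, rho: float = 0.8) -> np.ndarray:
    """AR(1) noise along the first (time) axis, unit marginal variance."""
    eps = rng.standard_normal(shape) * np.sqrt(1.0 - rho**2)
    return lfilter([1.0], [1.0, -rho], eps, axis=0)


def gen_met(
    grid: GridSpec,
    years,
    trend: Mapping[str, float] | None = None,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> MetSeries:
    """Generate daily meteorology: latitude-dependent seasonal harmonics,
    AR(1) weather noise, and an optional linear trend per variable.

    ``trend`` maps variable name to slope per decade (additive, variable
    units). With ``noise_scale=0`` the series is purely deterministic and
    every year is identical (given zero trends). Negative radiation produced
    by a trend is clamped to zero and logged.
    """
    years = year_array(years)
    trend = dict(trend or {})
    n_yr, n_pix = years.size, grid.n_pix
    lat = grid.lat_flat
    doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)

    peak_doy = np.where(lat >= 0.0, 200.0, 17.5)
    seasonal = np.cos(2.0 * np.pi * (doy[:, None] - peak_doy[None, :]) / DAYS_PER_YEAR)

    amp = 4.0 + 0.25 * np.abs(lat)
    tmean_clim = 27.0 - 0.55 * np.abs(lat) + amp[None, :] * seasonal  # (365, npix)

    ra = extraterrestrial_radiation(lat[None, :], doy[:, None])  # (365, npix)

    rng = np.random.default_rng(seed)
    shape = (n_yr * DAYS_PER_YEAR, n_pix)

    def noise(sd):
        if noise_scale == 0.0:
            return np.zeros((n_yr, DAYS_PER_YEAR, n_pix))
        return (sd * noise_scale * _ar1(rng, shape)).reshape(
            n_yr, DAYS_PER_YEAR, n_pix
        )

    dec = ((years - years[0]) / 10.0)[:, None, None]  # decades since start

    tmean = tmean_clim[None] + noise(2.0) + trend.get("tmax", 0.0) * 0.5 * dec \
        + trend.get("tmin", 0.0) * 0.5 * dec
    drange = np.maximum(10.0 + noise(1.5), 0.0)
    tmax = tmean + 0.5 * drange + (trend.get("tmax", 0.0) - trend.get("tmin", 0.0)) * 0.5 * dec
    tmin = tmax - drange

    clearness = np.clip(0.55 + noise(0.12), 0.05, 0.85)
    srad = ra[None] * clearness + trend.get("srad", 0.0) * dec
    if np.any(srad < 0):
        logger.warning("srad trend produced negative values; clamped to 0")
        srad = np.maximum(srad, 0.0)

    rh = np.clip(70.0 + noise(8.0) + trend.get("rh", 0.0) * dec, 0.0, 100.0)

    wet_mean = 3.0 * (1.0 + 0.4 * seasonal)[None]  # mm/d climatological mean
    if noise_scale == 0.0:
        precip = np.broadcast_to(wet_mean, (n_yr, DAYS_PER_YEAR, n_pix)).copy()
    else:
        wet = rng.random((n_yr, DAYS_PER_YEAR, n_pix)) < 0.35
        amount = rng.gamma(0.7, 1.0, size=(n_yr, DAYS_PER_YEAR, n_pix))
        precip = wet * amount * (wet_mean / (0.35 * 0.7))
    precip = np.maximum(precip + trend.get("precip", 0.0) * dec, 0.0)

    met = MetSeries(
        tmax=tmax.astype(np.float32),
        tmin=tmin.astype(np.float32),
        srad=srad.astype(np.float32),
        rh=rh.astype(np.float32),
        precip=precip.astype(np.float32),
    )
    met.validate()
    return met


def gen_lai(
    grid: GridSpec,
    years,
    composite_length: int = 16,
    trend=0.0,
    amplitude=0.8,
    noise_sd: float = 0.1,
    base=1.6,
    seed: int = 0,
    static: PixelStatic | None = None,
) -> LaiSeries:
    """Generate composite-period LAI with seasonality, a secular (greening)
    trend, and sampling noise.

    ``trend`` is m2/m2 per decade, scalar or per-pixel; ``amplitude`` the
    seasonal half-range; ``base`` the annual-mean starting level (scalar or
    per-pixel, must be non-negative). Values are floored at zero.
    """
    if composite_length not in (8, 16):
        raise ValueError("composite_length must be 8 or 16 days")
    if np.any(np.asarray(amplitude) < 0):
        raise ValueError("amplitude must be non-negative")
    if np.any(np.asarray(base) < 0):
        raise ValueError("negative base LAI rejected")
    years = year_array(years)
    n_pix = grid.n_pix
    lat = grid.lat_flat

    doys = np.arange(1, DAYS_PER_YEAR + 1 - composite_length // 2, composite_length)
    peak_doy = np.where(lat >= 0.0, 200.0, 17.5)
    seasonal = np.cos(2.0 * np.pi * (doys[:, None] - peak_doy[None, :]) / DAYS_PER_YEAR)

    trend = np.broadcast_to(np.asarray(trend, dtype=float), (n_pix,))
    base = np.broadcast_to(np.asarray(base, dtype=float), (n_pix,))
    dec = ((years - years[0]) / 10.0)[:, None, None]

    rng = np.random.default_rng(seed)
    noise = noise_sd * rng.standard_normal((years.size, doys.size, n_pix)) \
        if noise_sd > 0 else 0.0
    values = np.maximum(
        base[None, None, :]
        + amplitude * seasonal[None]
        + trend[None, None, :] * dec
        + noise,
        0.0,
    )
    lai = LaiSeries(
        values=values.astype(np.float32),
        composite_doys=doys,
        composite_length=composite_length,
    )
    lai.validate()
    return lai


def _annual_curve(years: np.ndarray, endpoints, anchors) -> np.ndarray:
    """Annual values: piecewise-linear through (year, value) anchors if
    given, else linear between the endpoint values."""
    if anchors is not None:
        ay = np.array([a[0] for a in anchors], dtype=float)
        av = np.array([a[1] for a in anchors], dtype=float)
        if np.any(np.diff(ay) <= 0):
            raise ValueError("anchor years must be strictly increasing")
        return np.interp(years.astype(float), ay, av)
    frac = (years - years[0]) / max(years[-1] - years[0], 1)
    return endpoints[0] + (endpoints[1] - endpoints[0]) * frac


def gen_drivers(
    years,
    co2_endpoints: tuple[float, float],
    ndep_endpoints_tg: tuple[float, float],
    grid: GridSpec,
    seed: int = 0,
    co2_anchors=None,
    ndep_anchors_tg=None,
) -> DriverRecord:
    """Generate annual drivers: CO2 linear between endpoints (or a
    piecewise-linear user curve through ``co2_anchors``); the global
    N-deposition total likewise (Tg N yr-1), disaggregated to pixels
    proportionally to a fixed seeded log-normal surface so that the
    area-weighted sum conserves the global total each year."""
    years = year_array(years)
    if co2_endpoints[0] <= 0 or co2_endpoints[1] <= 0:
        raise ValueError("CO2 endpoints must be positive")
    if ndep_endpoints_tg[0] <= 0 or ndep_endpoints_tg[1] <= 0:
        raise ValueError("N deposition endpoints must be positive")
    co2 = _annual_curve(years, co2_endpoints, co2_anchors)
    total_g = _annual_curve(years, ndep_endpoints_tg, ndep_anchors_tg) * 1.0e12

    rng = np.random.default_rng(seed)
    pattern = rng.lognormal(mean=0.0, sigma=0.8, size=grid.n_pix)
    weight = pattern / np.sum(pattern * grid.pixel_area)  # m-2
    ndep = total_g[:, None] * weight[None, :]  # g N m-2 yr-1

    drivers = DriverRecord(co2=co2, ndep=ndep)
    drivers.validate()
    return drivers


def gen_forcing(
    grid: GridSpec,
    static: PixelStatic,
    years,
    met_trend: Mapping[str, float] | None = None,
    lai_trend=0.028,
    composite_length: int = 16,
    co2_endpoints: tuple[float, float] = (340.13, 404.20),
    ndep_endpoints_tg: tuple[float, float] = (42.3, 58.9),
    seed: int = 0,
    noise_scale: float = 1.0,
    lai_noise_sd: float = 0.1,
    co2_anchors=None,
    ndep_anchors_tg=None,
) -> ForcingSet:
    """Convenience constructor bundling the generators into a ForcingSet.

    The default LAI trend (0.028 m2/m2 per decade) raises a 1.6 global mean
    by 0.1 over 36 years, matching the observed greening magnitude; CO2 and
    N-deposition endpoints default to the observed 1981/2016 values.
    """
    years = year_array(years)
    ss = np.random.SeedSequence(seed)
    s_met, s_lai, s_drv = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    met = gen_met(grid, years, trend=met_trend, seed=s_met, noise_scale=noise_scale)
    lai = gen_lai(grid, years, composite_length=composite_length, trend=lai_trend,
                  noise_sd=lai_noise_sd, seed=s_lai, static=static)
    drivers = gen_drivers(years, co2_endpoints, ndep_endpoints_tg, grid,
                          seed=s_drv, co2_anchors=co2_anchors,
                          ndep_anchors_tg=ndep_anchors_tg)
    return ForcingSet(grid=grid, static=static, years=years, met=met, lai=lai,
                      drivers=drivers)


def composite_to_daily(lai: LaiSeries) -> np.ndarray:
    """Interpolate composite-period LAI to daily values.

    Linear interpolation between composite dates across year boundaries,
    constant extrapolation before the first and after the last composite.
    Returns (n_years, 365, n_pix), non-negative.
    """
    lai.validate()
    values = np.asarray(lai.values, dtype=np.float32)
    n_yr, n_comp, n_pix = values.shape
    if n_yr * n_comp < 2:
        logger.warning("single composite date: returning a constant series")
        return np.broadcast_to(values[:, :1, :],
                               (n_yr, DAYS_PER_YEAR, n_pix)).copy()
    t_comp = (np.arange(n_yr)[:, None] * DAYS_PER_YEAR
              + lai.composite_doys[None, :]).ravel().astype(float)
    flat = values.reshape(n_yr * n_comp, n_pix)
    t_out = np.arange(1, n_yr * DAYS_PER_YEAR + 1, dtype=float)
    # np.interp per pixel would be O(n_pix) python; use searchsorted once
    idx = np.clip(np.searchsorted(t_comp, t_out) - 1, 0, t_comp.size - 2)
    t0, t1 = t_comp[idx], t_comp[idx + 1]
    w = np.clip((t_out - t0) / (t1 - t0), 0.0, 1.0)[:, None].astype(np.float32)
    daily = (1.0 - w) * flat[idx] + w * flat[idx + 1]
    return np.maximum(daily.reshape(n_yr, DAYS_PER_YEAR, n_pix), 0.0)


def lai_climatology(lai: LaiSeries, years: np.ndarray,
                    window: tuple[int, int]) -> np.ndarray:
    """Mean LAI per composite date over a window of years: (n_comp, n_pix)."""
    sel = (years >= window[0]) & (years <= window[1])
    if not np.any(sel):
        raise ValueError(f"window {window} not covered by forcing years")
    return np.asarray(lai.values[sel].mean(axis=0))


def make_baseline(forcing: ForcingSet, spec: ScenarioSpec) -> ForcingSet:
    """Construct baseline-scenario forcing per the factorial design.

    For drivers with mode ``baseline``: CO2 and N deposition are frozen at
    their value in the first simulated year; LAI is replaced (in every year)
    by the composite-date climatology over ``baseline_lai_window``, so
    canopy seasonality is preserved while the trend vanishes; meteorology of
    each simulated year is replaced by a whole calendar year drawn uniformly
    with replacement (seeded) from ``climate_resample_window``, the same
    drawn year applied to all pixels. Drivers with mode ``transient`` are
    untouched. The operation is idempotent at fixed seed.
    """
    period = spec.period or (int(forcing.years[0]), int(forcing.years[-1]))
    y0, y1 = period
    if y0 < forcing.years[0] or y1 > forcing.years[-1]:
        raise ValueError(f"period {period} not covered by forcing")
    if spec.modes["lai"] == "baseline" and spec.baseline_lai_window[1] > y1:
        raise ValueError("baseline LAI window must not extend past the period")
    if spec.modes["climate"] == "baseline":
        w0, w1 = spec.climate_resample_window
        if w0 < forcing.years[0] or w1 >= y0:
            raise ValueError("climate resample window must precede the "
                             "simulation period and be covered by forcing")
    if spec.all_transient():
        return forcing

    out = forcing.copy()
    sim = (out.years >= y0) & (out.years <= y1)
    i0 = out.year_index(y0)

    if spec.modes["co2"] == "baseline":
        out.drivers.co2[sim] = out.drivers.co2[i0]
    if spec.modes["ndep"] == "baseline":
        out.drivers.ndep[sim] = out.drivers.ndep[i0]
    if spec.modes["lai"] == "baseline":
        clim = lai_climatology(out.lai, out.years, spec.baseline_lai_window)
        out.lai.values[:] = clim[None].astype(out.lai.values.dtype)
    if spec.modes["climate"] == "baseline":
        rng = np.random.default_rng(spec.seed)
        w0, w1 = spec.climate_resample_window
        pool = np.arange(out.year_index(w0), out.year_index(w1) + 1)
        drawn = rng.choice(pool, size=int(sim.sum()), replace=True)
        sim_idx = np.flatnonzero(sim)
        for var in MET_VARS:
            arr = getattr(out.met, var)
            arr[sim_idx] = getattr(forcing.met, var)[drawn]
    return out
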