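"""Gridded NetCDF I/O (CF-style), state checkpoints, and forcing export.

Files use dimension order (time, lat, lon), pixel-center coordinates with
north-to-south rows, time in days since a fixed epoch on a 365-day
calendar, and mandatory ``units`` attributes. Written with xarray's scipy
backend (NetCDF3 classic), which round-trips 64-bit floats exactly.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from ecosink.forcing import (
    MET_VARS,
    DriverRecord,
    ForcingSet,
    LaiSeries,
    MetSeries,
)
from ecosink.grid import GridSpec, PixelStatic
from ecosink.params import N_POOLS, POOL_NAMES
from ecosink.pools import EcosystemState
from ecosink.units import DAYS_PER_YEAR

ENGINE = "scipy"
EPOCH_YEAR = 1901

MET_UNITS = {"tmax": "degC", "tmin": "degC", "srad": "MJ m-2 d-1",
             "rh": "percent", "precip": "mm d-1"}


def _grid_coords(grid: GridSpec) -> dict:
    return {"lat": ("lat", np.asarray(grid.lat_centers, dtype=float),
                    {"units": "degrees_north"}),
            "lon": ("lon", np.asarray(grid.lon_centers, dtype=float),
                    {"units": "degrees_east"})}


def _to_latlon(grid: GridSpec, flat: np.ndarray) -> np.ndarray:
    """Reshape trailing flat pixel axis to (lat, lon)."""
    return np.asarray(flat).reshape(*flat.shape[:-1], grid.n_lat, grid.n_lon)


def write_grids(data: xr.Dataset, path) -> None:
    """Write a CF-style dataset; every data variable must carry a ``units``
    attribute and use (time, lat, lon) (or a subset) dimension order."""
    for name, var in data.data_vars.items():
        if "units" not in var.attrs:
            raise ValueError(f"variable {name!r} is missing a units attribute")
        if "lat" in var.dims and "lon" in var.dims \
                and tuple(var.dims[-2:]) != ("lat", "lon"):
            raise ValueError(f"variable {name!r} has non-canonical dimension "
                             f"order {var.dims}; expected (..., lat, lon)")
    data.to_netcdf(path, engine=ENGINE)


def read_grids(path, variables=None) -> xr.Dataset:
    """Read a gridded dataset, validating units attributes."""
    ds = xr.open_dataset(path, engine=ENGINE).load()
    names = variables if variables is not None else list(ds.data_vars)
    for name in names:
        if "units" not in ds[name].attrs:
            raise ValueError(f"variable {name!r} is missing a units attribute")
    return ds


def forcing_to_dataset(forcing: ForcingSet) -> xr.Dataset:
    """Bundle a ForcingSet into one CF-style dataset (met at daily
    resolution, LAI at composite dates, drivers annual)."""
    grid = forcing.grid
    n_yr = forcing.years.size
    time = ((forcing.years[:, None] - EPOCH_YEAR) * DAYS_PER_YEAR
            + np.arange(DAYS_PER_YEAR)[None, :]).ravel()
    data = {}
    for var in MET_VARS:
        arr = _to_latlon(grid, getattr(forcing.met, var)).reshape(
            n_yr * DAYS_PER_YEAR, grid.n_lat, grid.n_lon)
        data[var] = xr.DataArray(arr, dims=("time", "lat", "lon"),
                                 attrs={"units": MET_UNITS[var]})
    n_comp = forcing.lai.composite_doys.size
    lai_time = ((forcing.years[:, None] - EPOCH_YEAR) * DAYS_PER_YEAR
                + forcing.lai.composite_doys[None, :] - 1).ravel()
    lai = _to_latlon(grid, forcing.lai.values).reshape(
        n_yr * n_comp, grid.n_lat, grid.n_lon)
    ds = xr.Dataset(
        {name: da for name, da in data.items()},
        coords={**{k: v for k, v in _grid_coords(grid).items()},
                "time": ("time", time,
                         {"units": f"days since {EPOCH_YEAR}-01-01",
                          "calendar": "365_day"})})
    ds["lai"] = xr.DataArray(
        lai, dims=("lai_time", "lat", "lon"),
        coords={"lai_time": ("lai_time", lai_time,
                             {"units": f"days since {EPOCH_YEAR}-01-01"})},
        attrs={"units": "m2 m-2",
               "composite_length_days": forcing.lai.composite_length})
    ds["co2"] = xr.DataArray(forcing.drivers.co2, dims=("year",),
                             coords={"year": forcing.years},
                             attrs={"units": "ppm"})
    ds["ndep"] = xr.DataArray(
        _to_latlon(grid, forcing.drivers.ndep), dims=("year", "lat", "lon"),
        attrs={"units": "g N m-2 yr-1"})
    for var, arr in (("omega", forcing.static.omega),
                     ("pft", forcing.static.pft.astype(float)),
                     ("clay", forcing.static.clay),
                     ("silt", forcing.static.silt),
                     ("sand", forcing.static.sand),
                     ("pixel_area", grid.pixel_area)):
        ds[var] = xr.DataArray(_to_latlon(grid, arr), dims=("lat", "lon"),
                               attrs={"units": "1" if var != "pixel_area"
                                      else "m2"})
    return ds


def dataset_to_forcing(ds: xr.Dataset) -> ForcingSet:
    """Inverse of :func:`forcing_to_dataset`."""
    n_lat, n_lon = ds.sizes["lat"], ds.sizes["lon"]
    years = np.asarray(ds["year"].values, dtype=int)
    n_yr = years.size
    grid = GridSpec(
        n_lat=n_lat, n_lon=n_lon,
        lat_centers=np.asarray(ds["lat"].values, dtype=float),
        lon_centers=np.asarray(ds["lon"].values, dtype=float),
        pixel_area=np.asarray(ds["pixel_area"].values, dtype=float).ravel())
    static = PixelStatic(
        omega=np.asarray(ds["omega"].values).ravel(),
        pft=np.asarray(ds["pft"].values).ravel().astype(int),
        clay=np.asarray(ds["clay"].values).ravel(),
        silt=np.asarray(ds["silt"].values).ravel(),
        sand=np.asarray(ds["sand"].values).ravel(),
        latitude=grid.lat_flat)
    met = MetSeries(**{
        var: np.asarray(ds[var].values, dtype=np.float32).reshape(
            n_yr, DAYS_PER_YEAR, n_lat * n_lon) for var in MET_VARS})
    lai_vals = np.asarray(ds["lai"].values, dtype=np.float32)
    n_comp = lai_vals.shape[0] // n_yr
    doys = (np.asarray(ds["lai_time"].values[:n_comp], dtype=int)
            % DAYS_PER_YEAR) + 1
    lai = LaiSeries(
        values=lai_vals.reshape(n_yr, n_comp, n_lat * n_lon),
        composite_doys=doys,
        composite_length=int(ds["lai"].attrs["composite_length_days"]))
    drivers = DriverRecord(
        co2=np.asarray(ds["co2"].values, dtype=float),
        ndep=np.asarray(ds["ndep"].values, dtype=float).reshape(
            n_yr, n_lat * n_lon))
    return ForcingSet(grid=grid, static=static, years=years, met=met,
                      lai=lai, drivers=drivers)


STATE_FIELDS = ("mineral_n", "leaf_n", "soil_water", "water_capacity", "tsoil")
STATE_UNITS = {"mineral_n": "g N m-2", "leaf_n": "g N m-2",
               "soil_water": "mm", "water_capacity": "mm", "tsoil": "degC"}


def write_state(state: EcosystemState, grid: GridSpec, path) -> None:
    """Checkpoint all pools + N + water per pixel; 64-bit, bit-exact
    round-trip (write -> read -> step equals step directly)."""
    ds = xr.Dataset(coords={k: v for k, v in _grid_coords(grid).items()})
    ds["pools"] = xr.DataArray(
        _to_latlon(grid, state.pools), dims=("pool", "lat", "lon"),
        coords={"pool": list(POOL_NAMES)}, attrs={"units": "g C m-2"})
    for name in STATE_FIELDS:
        ds[name] = xr.DataArray(_to_latlon(grid, getattr(state, name)),
                                dims=("lat", "lon"),
                                attrs={"units": STATE_UNITS[name]})
    ds.to_netcdf(path, engine=ENGINE)


def read_state(path) -> EcosystemState:
    ds = xr.open_dataset(path, engine=ENGINE).load()
    n_pix = ds.sizes["lat"] * ds.sizes["lon"]
    return EcosystemState(
        pools=np.asarray(ds["pools"].values, dtype=float).reshape(N_POOLS, n_pix),
        **{name: np.asarray(ds[name].values, dtype=float).ravel()
           for name in STATE_FIELDS})
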