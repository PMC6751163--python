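"""Grid geometry and static per-pixel attributes.

Pixels are stored flat (row-major, north-to-south rows); ``GridSpec`` holds
the geometry and cos-latitude-weighted areas, ``PixelStatic`` the
time-invariant attributes the model needs per pixel (clumping index, land
cover class, soil texture).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ecosink.units import EARTH_RADIUS_M


@dataclass
class GridSpec:
    """Regular lat/lon grid with pixel-center coordinates.

    Areas follow the spherical-rectangle formula
    ``area = R^2 * dlat * dlon * cos(lat)`` so a pixel at higher |lat| is
    never larger than one at lower |lat|.
    """

    n_lat: int
    n_lon: int
    lat_centers: np.ndarray  # degrees, north-to-south
    lon_centers: np.ndarray  # degrees
    pixel_area: np.ndarray = field(repr=False)  # m^2, flat (n_lat*n_lon,)

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must have at least one pixel")
        lat = np.asarray(self.lat_centers, dtype=float)
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitudes must lie in [-90, 90]")
        if np.any(self.pixel_area <= 0):
            raise ValueError("pixel areas must be positive")

    @property
    def n_pix(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def lat_flat(self) -> np.ndarray:
        """Per-pixel latitude, degrees, flat row-major order."""
        return np.repeat(np.asarray(self.lat_centers, dtype=float), self.n_lon)


@dataclass
class PixelStatic:
    """Static per-pixel attributes: clumping index Omega in (0, 1], land
    cover class, soil texture fractions (clay + silt + sand = 1), latitude."""

    omega: np.ndarray
    pft: np.ndarray  # integer land-cover class
    clay: np.ndarray
    silt: np.ndarray
    sand: np.ndarray
    latitude: np.ndarray  # degrees

    def __post_init__(self) -> None:
        if np.any(self.omega <= 0) or np.any(self.omega > 1):
            raise ValueError("clumping index must lie in (0, 1]")
        tex = self.clay + self.silt + self.sand
        if np.any(self.clay < 0) or np.any(self.silt < 0) or np.any(self.sand < 0):
            raise ValueError("texture fractions must be non-negative")
        if np.any(np.abs(tex - 1.0) > 1e-8):
            raise ValueError("texture fractions must sum to 1")

    @property
    def n_pix(self) -> int:
        return self.omega.size


def gen_grid(
    n_lat: int,
    n_lon: int,
    lat_range: tuple[float, float] = (-60.0, 75.0),
    seed: int = 0,
) -> tuple[GridSpec, PixelStatic]:
    """Generate a synthetic grid with static pixel attributes.

    Clumping index is drawn uniformly in [0.5, 0.95]; soil texture fractions
    are Dirichlet-distributed (normalized to 1); land-cover classes are
    assigned at random from three classes. Deterministic given ``seed``.

    Parameters
    ----------
    n_lat, n_lon
        Grid dimensions (>= 1 each).
    lat_range
        (south, north) edges in degrees; must be increasing and within
        [-90, 90].
    seed
        RNG seed; identical seeds yield identical grids.
    """
    if n_lat < 1 or n_lon < 1:
        raise ValueError("empty grid: n_lat and n_lon must be >= 1")
    lo, hi = lat_range
    if not (lo < hi):
        raise ValueError(f"inverted lat_range {lat_range}")
    if lo < -90.0 or hi > 90.0:
        raise ValueError("lat_range must lie within [-90, 90]")

    dlat = (hi - lo) / n_lat
    # north-to-south row order
    lat_centers = (lo + dlat * (np.arange(n_lat) + 0.5))[::-1].copy()
    dlon = 360.0 / max(n_lon, 1)
    lon_centers = -180.0 + dlon * (np.arange(n_lon) + 0.5)

    dlat_r = np.deg2rad(dlat)
    dlon_r = np.deg2rad(dlon)
    area_by_lat = (
        EARTH_RADIUS_M**2 * dlat_r * dlon_r * np.cos(np.deg2rad(lat_centers))
    )
    pixel_area = np.repeat(area_by_lat, n_lon)

    grid = GridSpec(
        n_lat=n_lat,
        n_lon=n_lon,
        lat_centers=lat_centers,
        lon_centers=lon_centers,
        pixel_area=pixel_area,
    )

    rng = np.random.default_rng(seed)
    n_pix = n_lat * n_lon
    omega = rng.uniform(0.5, 0.95, size=n_pix)
    tex = rng.dirichlet(np.array([4.0, 6.0, 8.0]), size=n_pix)
    pft = rng.integers(0, 3, size=n_pix)
    static = PixelStatic(
        omega=omega,
        pft=pft,
        clay=tex[:, 0],
        silt=tex[:, 1],
        sand=tex[:, 2],
        latitude=grid.lat_flat,
    )
    return grid, static
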