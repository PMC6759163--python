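"""Bathymetry grids: depth lookup and a synthetic shelf-to-abyss generator.

Depths are metres, negative below sea level.  The shelf/oceanic habitat
split used downstream is -2200 m (mean ARS depth below -2200 m = oceanic
waters; at or above = shelf/shelf-edge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator


@dataclass
class DepthGrid:
    """Regular lat/lon grid of depth values (m, negative below sea level)."""

    lats: np.ndarray  # ascending, degrees
    lons: np.ndarray  # ascending, degrees
    depth: np.ndarray  # shape (len(lats), len(lons))

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(np.diff(self.lats) <= 0) or np.any(np.diff(self.lons) <= 0):
            raise ValueError("grid axes must be strictly ascending")
        if self.depth.shape != (len(self.lats), len(self.lons)):
            raise ValueError("depth shape does not match grid axes")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depth grid contains non-finite values")

    def interpolate(self, lat, lon, method: str = "linear") -> np.ndarray:
        """Depth at query points; bilinear by default, ``nearest`` optional.

        Raises a ValueError naming the first offending point when a query
        falls outside the grid extent.
        """
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        out_lat = (lat < self.lats[0]) | (lat > self.lats[-1])
        out_lon = (lon < self.lons[0]) | (lon > self.lons[-1])
        bad = np.flatnonzero(out_lat | out_lon)
        if bad.size:
            b = bad[0]
            raise ValueError(
                f"fix {b} at ({lat[b]:.4f}, {lon[b]:.4f}) lies outside the "
                f"bathymetry grid extent"
            )
        itp = RegularGridInterpolator(
            (self.lats, self.lons), self.depth, method=method
        )
        return itp(np.column_stack([lat, lon]))


def synthetic_bathymetry(
    lat_range: tuple[float, float] = (-56.0, -36.0),
    lon_range: tuple[float, float] = (38.0, 66.0),
    cell_deg: float = 0.1,
    shelf_depth: float = -300.0,
    abyss_depth: float = -4200.0,
    shelf_center: tuple[float, float] = (-46.35, 51.70),
    shelf_radius_km: float = 150.0,
    slope_width_km: float = 60.0,
) -> DepthGrid:
    """Smooth synthetic shelf-to-abyss gradient for tests and simulations.

    A circular shelf plateau around ``shelf_center`` (the colony, by
    default) falls off through a logistic slope to abyssal depth, emulating
    an island shelf surrounded by oceanic waters.  Purely synthetic — not a
    model of any real relief.
    """
    lats = np.arange(lat_range[0], lat_range[1] + cell_deg / 2, cell_deg)
    lons = np.arange(lon_range[0], lon_range[1] + cell_deg / 2, cell_deg)
    glon, glat = np.meshgrid(lons, lats)
    # small-angle planar distance is fine for a smooth synthetic surface
    dlat = (glat - shelf_center[0]) * 111.195
    dlon = (glon - shelf_center[1]) * 111.195 * np.cos(np.radians(shelf_center[0]))
    dist = np.hypot(dlat, dlon)
    frac = 1.0 / (1.0 + np.exp(-(dist - shelf_radius_km) / slope_width_km))
    depth = shelf_depth + (abyss_depth - shelf_depth) * frac
    return DepthGrid(lats=lats, lons=lons, depth=depth)


def uniform_bathymetry(
    depth: float,
    lat_range: tuple[float, float] = (-90.0, 90.0),
    lon_range: tuple[float, float] = (-180.0, 180.0),
) -> DepthGrid:
    """Flat-bottom grid, handy for exercising the habitat rule in isolation."""
    lats = np.linspace(lat_range[0], lat_range[1], 11)
    lons = np.linspace(lon_range[0], lon_range[1], 11)
    return DepthGrid(lats=lats, lons=lons, depth=np.full((11, 11), float(depth)))
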