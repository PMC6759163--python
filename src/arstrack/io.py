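"""File formats: track CSV, patch CSV/GeoJSON, depth rasters.

The track CSV schema is the surrogate for the radar-GPS logger output:
columns ``bird_id, time (ISO-8601 UTC), lat, lon, radar_count``, sorted by
(bird_id, time), one header row.  Rasters are read from ESRI ASCII grids
or NetCDF3 files with 1-D ``lat``/``lon`` coordinate variables.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .bathymetry import DepthGrid
from .tracks import ARSPatch, Encounter, Track

TRACK_CSV_COLUMNS = ["bird_id", "time", "lat", "lon", "radar_count"]


def read_track_csv(path, colony: tuple[float, float]) -> list[Track]:
    """Read and validate a multi-bird track CSV into Track objects."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    try:
        df["time"] = pd.to_datetime(df["time"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable time column: {exc}") from exc
    tracks = []
    for bird_id, g in df.groupby("bird_id", sort=False):
        t = pd.DatetimeIndex(g["time"]).asi8
        if np.any(np.diff(t) < 0):
            raise ValueError(f"{path}: rows for bird '{bird_id}' not sorted by time")
        if g["time"].duplicated().any():
            line = int(g.index[g["time"].duplicated()][0]) + 2  # header + 1-based
            raise ValueError(
                f"{path}: duplicate timestamp for bird '{bird_id}' at line {line}"
            )
        fixes = g[["time", "lat", "lon", "radar_count"]].reset_index(drop=True)
        tracks.append(Track(bird_id=str(bird_id), fixes=fixes, colony=colony))
    return tracks


def write_track_csv(tracks: list[Track], path) -> None:
    frames = []
    for tr in tracks:
        f = tr.fixes.copy()
        f.insert(0, "bird_id", tr.bird_id)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False, float_format="%.6f")


def write_patches_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in ("start", "end"):
        if col in out:
            out[col] = pd.DatetimeIndex(out[col]).strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False, float_format="%.6f")


def write_encounters_csv(encounters: list[Encounter], path) -> None:
    rows = [
        {
            "bird_id": e.bird_id,
            "start": e.start.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "end": e.end.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "n_detections": e.n_detections,
        }
        for e in encounters
    ]
    pd.DataFrame(rows, columns=["bird_id", "start", "end", "n_detections"]).to_csv(
        path, index=False
    )


def write_patches_geojson(
    patches: list[ARSPatch], tracks: dict[str, Track], path,
    properties: pd.DataFrame | None = None,
) -> None:
    """One LineString feature per patch (the member fixes), descriptors as
    properties when a descriptor table is supplied (row-aligned)."""
    features = []
    for i, p in enumerate(patches):
        tr = tracks[p.bird_id]
        sub = tr.fixes.iloc[p.fix_indices]
        coords = [
            [round(float(x), 6), round(float(y), 6)]
            for x, y in zip(sub["lon"], sub["lat"])
        ]
        props = {
            "bird_id": p.bird_id,
            "scale_class": p.scale_class,
            "start": p.start.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "end": p.end.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "radii_km": list(p.radii_km),
        }
        if properties is not None and i < len(properties):
            row = properties.iloc[i].to_dict()
            for k, v in row.items():
                if k in ("start", "end"):
                    continue
                if isinstance(v, (np.floating, np.integer)):
                    v = v.item()
                elif isinstance(v, pd.Timestamp):
                    v = v.strftime("%Y-%m-%dT%H:%M:%S%z")
                elif isinstance(v, (np.bool_,)):
                    v = bool(v)
                props[k] = None if (isinstance(v, float) and np.isnan(v)) else v
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


# ---------------------------------------------------------------------------
# Depth rasters
# ---------------------------------------------------------------------------

def read_depth_raster(path) -> DepthGrid:
    """Read a bathymetry grid from ESRI ASCII (.asc) or NetCDF3 (.nc).

    NetCDF files must carry geographic 1-D ``lat`` and ``lon`` coordinates
    (any projected CRS is rejected).
    """
    path = str(path)
    if path.endswith(".asc"):
        return _read_esri_ascii(path)
    if path.endswith(".nc"):
        return _read_netcdf(path)
    raise ValueError(f"{path}: unsupported raster format (use .asc or .nc)")


def _read_esri_ascii(path) -> DepthGrid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ESRI ASCII header missing '{key}'")
    data = np.concatenate(rows).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    if nodata is not None and np.any(data == nodata):
        raise ValueError(f"{path}: grid contains nodata cells")
    cell = header["cellsize"]
    x0 = header.get("xllcenter", header.get("xllcorner", 0.0) + cell / 2)
    y0 = header.get("yllcenter", header.get("yllcorner", 0.0) + cell / 2)
    lons = x0 + cell * np.arange(int(header["ncols"]))
    lats = y0 + cell * np.arange(int(header["nrows"]))
    if lats[-1] > 90 or lons[-1] > 360:
        raise ValueError(f"{path}: grid coordinates are not geographic lat/lon")
    # ASCII grids store north-up: first row = northernmost
    return DepthGrid(lats=lats, lons=lons, depth=data[::-1, :])


def _read_netcdf(path) -> DepthGrid:
    from scipy.io import netcdf_file

    with netcdf_file(path, "r", mmap=False) as nc:
        names = {n.lower(): n for n in nc.variables}
        lat_name = names.get("lat") or names.get("latitude")
        lon_name = names.get("lon") or names.get("longitude")
        if lat_name is None or lon_name is None:
            raise ValueError(
                f"{path}: no geographic lat/lon coordinates (projected CRS rejected)"
            )
        lats = np.array(nc.variables[lat_name][:], dtype=float)
        lons = np.array(nc.variables[lon_name][:], dtype=float)
        depth_name = next(
            (n for n in nc.variables if n not in (lat_name, lon_name)), None
        )
        if depth_name is None:
            raise ValueError(f"{path}: no depth variable found")
        depth = np.array(nc.variables[depth_name][:], dtype=float)
    if lats[0] > lats[-1]:
        lats, depth = lats[::-1], depth[::-1, :]
    return DepthGrid(lats=lats, lons=lons, depth=depth)


def write_esri_ascii(grid: DepthGrid, path) -> None:
    cell = float(grid.lats[1] - grid.lats[0])
    with open(path, "w") as fh:
        fh.write(f"ncols {len(grid.lons)}\n")
        fh.write(f"nrows {len(grid.lats)}\n")
        fh.write(f"xllcenter {grid.lons[0]:.6f}\n")
        fh.write(f"yllcenter {grid.lats[0]:.6f}\n")
        fh.write(f"cellsize {cell:.6f}\n")
        for row in grid.depth[::-1, :]:
            fh.write(" ".join(f"{v:.1f}" for v in row) + "\n")
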