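"""Track quality control, equal-distance resampling and day/night split.

The preprocessing chain mirrors standard biologging practice for albatross
GPS tracks: implausible fixes (ground speed above 100 km/h) are removed,
tracks are re-discretised to one vertex per kilometre of path so that
first-passage-time profiles are comparable across trips, and fixes are
classified day/night by geometric solar elevation against the civil-twilight
threshold of -6 degrees.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .tracks import DaylightMask, ResampledPath, Track

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of degrees.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding overflow for antipodal / identical points
    central = 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return EARTH_RADIUS_KM * central


def step_speeds_kmh(track: Track) -> np.ndarray:
    """Speed over each consecutive-fix interval (km/h), length n-1."""
    d = haversine_km(track.lat[:-1], track.lon[:-1], track.lat[1:], track.lon[1:])
    dt_h = np.diff(track.times.asi8) / 3.6e12
    return d / dt_h


def filter_speed(track: Track, vmax: float = 100.0) -> Track:
    """Remove fixes implying ground speeds above ``vmax`` km/h.

    Removal is iterative: whenever the speed from the last retained fix to
    the candidate fix exceeds ``vmax`` the *later* fix is dropped and the
    speed is recomputed against the next candidate, until no consecutive
    pair is too fast.  The first fix is always kept.  Idempotent.
    """
    lat, lon = track.lat, track.lon
    t = track.times.asi8  # ns
    n = len(track)
    keep = [0]
    for i in range(1, n):
        j = keep[-1]
        d = haversine_km(lat[j], lon[j], lat[i], lon[i])
        dt_h = (t[i] - t[j]) / 3.6e12
        if d / dt_h <= vmax:
            keep.append(i)
    if len(keep) < 2:
        raise ValueError(
            f"speed filter at {vmax} km/h left fewer than 2 fixes: unusable trip"
        )
    if len(keep) < n:
        log.info("speed filter removed %d of %d fixes", n - len(keep), n)
    fixes = track.fixes.iloc[keep].reset_index(drop=True)
    return Track(track.bird_id, fixes, track.colony)


def _to_unit(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    la, lo = np.radians(lat), np.radians(lon)
    return np.stack(
        [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=-1
    )


def _from_unit(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lat, lon


def resample_equal_distance(track: Track, step_km: float = 1.0) -> ResampledPath:
    """Place vertices every ``step_km`` of along-path great-circle distance.

    Vertex 0 sits on the first fix; vertex i at along-path distance
    ``i * step_km`` (spherical interpolation within the containing leg); the
    trailing partial segment is dropped.  Vertex times are interpolated
    linearly in distance within each leg (constant speed per leg).
    """
    if step_km <= 0:
        raise ValueError("step_km must be positive")
    lat, lon = track.lat, track.lon
    leg = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    cum = np.concatenate([[0.0], np.cumsum(leg)])
    total = cum[-1]
    if total < step_km:
        raise ValueError(
            f"path length {total:.3f} km is shorter than one step of {step_km} km"
        )
    n_vertices = int(math.floor(total / step_km + 1e-9)) + 1
    targets = np.arange(n_vertices) * step_km
    # leg index such that cum[j] <= target < cum[j+1]
    j = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(leg) - 1)
    leg_len = leg[j]
    frac = np.where(leg_len > 0, (targets - cum[j]) / np.where(leg_len > 0, leg_len, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)

    a = _to_unit(lat[j], lon[j])
    b = _to_unit(lat[j + 1], lon[j + 1])
    dot = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    theta = np.arccos(dot)
    sin_t = np.sin(theta)
    small = sin_t < 1e-12
    w_a = np.where(small, 1.0 - frac, np.sin((1.0 - frac) * theta) / np.where(small, 1.0, sin_t))
    w_b = np.where(small, frac, np.sin(frac * theta) / np.where(small, 1.0, sin_t))
    v = a * w_a[:, None] + b * w_b[:, None]
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    vlat, vlon = _from_unit(v)

    t_ns = track.times.asi8
    vt = t_ns[j] + (frac * (t_ns[j + 1] - t_ns[j])).astype(np.int64)
    vertices = pd.DataFrame(
        {
            "lat": vlat,
            "lon": vlon,
            "time": pd.DatetimeIndex(vt.astype("datetime64[ns]")).tz_localize("UTC"),
            "dist_km": targets,
            "leg": j,
        }
    )
    return ResampledPath(vertices=vertices, step_km=step_km)


# ---------------------------------------------------------------------------
# Solar geometry (NOAA low-accuracy equations; geometric elevation, no
# atmospheric refraction).  Accurate to ~0.1 degrees for 1900-2100.
# ---------------------------------------------------------------------------

def _julian_century(times_ns: np.ndarray) -> np.ndarray:
    jd = times_ns / 86400.0e9 + 2440587.5
    return (jd - 2451545.0) / 36525.0


def solar_elevation(time, lat, lon) -> np.ndarray | float:
    """Geometric solar elevation in degrees at UTC ``time`` and position.

    ``time`` may be anything pandas parses to timestamps (scalar or array);
    ``lat``/``lon`` broadcast against it.
    """
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(time, dtype="object")))
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    t_ns = idx.tz_convert("UTC").asi8.astype(float)
    jc = _julian_century(t_ns)

    l0 = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = np.radians(m)
    c = (
        np.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)

    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    lam = np.radians(app_long)
    decl = np.arcsin(np.sin(eps) * np.sin(lam))

    y = np.tan(eps / 2.0) ** 2
    l0r = np.radians(l0)
    eqtime = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * e * np.sin(mr)
        + 4.0 * e * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * e * e * np.sin(2 * mr)
    )

    minutes_utc = np.mod(t_ns / 1e9, 86400.0) / 60.0
    lon_arr = np.asarray(lon, dtype=float)
    lat_arr = np.asarray(lat, dtype=float)
    tst = np.mod(minutes_utc + eqtime + 4.0 * lon_arr, 1440.0)
    ha = tst / 4.0 - 180.0
    ha = np.where(ha < -180.0, ha + 360.0, ha)

    phi = np.radians(lat_arr)
    har = np.radians(ha)
    cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(har)
    elev = 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    if np.ndim(time) == 0 and np.isscalar(lat):
        return float(elev[0])
    return elev


def daylight_mask(track: Track, threshold: float = -6.0) -> DaylightMask:
    """Day flag per fix: sun at or above ``threshold`` degrees elevation.

    Evaluated at each fix's own position and time (trips span tens of
    degrees of longitude, so the colony's clock is not a valid proxy).
    """
    elev = solar_elevation(track.fixes["time"], track.lat, track.lon)
    return DaylightMask(day=np.asarray(elev) >= threshold, twilight_threshold=threshold)


def split_daylight_subtracks(track: Track, mask: DaylightMask) -> list[Track]:
    """Maximal daytime runs of a track, as independent tracks.

    Runs of a single fix cannot form a trajectory and are dropped (logged).
    The night gaps between the returned subtracks define the "days" used
    for small-scale FPT thresholds.
    """
    if len(mask) != len(track):
        raise ValueError("mask and track have different lengths")
    day = np.asarray(mask.day, dtype=bool)
    subtracks: list[Track] = []
    n = len(track)
    i = 0
    while i < n:
        if not day[i]:
            i += 1
            continue
        jj = i
        while jj + 1 < n and day[jj + 1]:
            jj += 1
        if jj > i:
            fixes = track.fixes.iloc[i : jj + 1].reset_index(drop=True)
            subtracks.append(Track(track.bird_id, fixes, track.colony))
        else:
            log.debug("dropping single-fix daylight run at fix %d", i)
        i = jj + 1
    return subtracks
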