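"""Per-ARS behavioural descriptors, radar encounters and trip summaries.

Each detected ARS patch gets the descriptor set used to contrast natural
and boat-associated search: duration, sinuosity, mean distance to the
colony, mean depth and the shelf/oceanic habitat class, proportion of time
sitting on the water (< 10 km/h), proportion at night (large scales only),
nesting, and the radar-based boat association.  Boat association and
encounters are computed on the ORIGINAL fixes by time interval — radar
counts are never carried onto resampled vertices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bathymetry import DepthGrid
from .detect import compute_nesting
from .preprocess import haversine_km
from .tracks import ARSPatch, DaylightMask, Encounter, Track, interval_total_hours

log = logging.getLogger(__name__)

DEPTH_CUTOFF_M = -2200.0
ON_WATER_KMH = 10.0
ENCOUNTER_GAP_H = 2.0


def sinuosity(lat, lon) -> float:
    """1 - (straight first-to-last distance) / (total path distance).

    0 for a perfectly straight path, 1 for a closed loop.  A stationary
    path (zero total distance) is defined as 0 and logged.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(lat) < 2:
        raise ValueError("sinuosity needs at least 2 fixes")
    total = float(np.sum(haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))
    if total <= 0:
        log.info("stationary path: sinuosity defined as 0")
        return 0.0
    straight = float(haversine_km(lat[0], lon[0], lat[-1], lon[-1]))
    return 1.0 - straight / total


def _interval_hours(times: pd.DatetimeIndex) -> np.ndarray:
    return np.diff(times.asi8) / 3.6e12


def prop_on_water(fixes: pd.DataFrame, v_thresh: float = ON_WATER_KMH) -> float:
    """Duration-weighted fraction of inter-fix intervals slower than ``v_thresh``."""
    if len(fixes) < 2:
        raise ValueError("prop_on_water needs at least 2 fixes")
    times = pd.DatetimeIndex(fixes["time"])
    dt = _interval_hours(times)
    d = haversine_km(
        fixes["lat"].to_numpy()[:-1],
        fixes["lon"].to_numpy()[:-1],
        fixes["lat"].to_numpy()[1:],
        fixes["lon"].to_numpy()[1:],
    )
    speeds = d / dt
    slow = speeds < v_thresh
    return float(np.sum(dt[slow]) / np.sum(dt))


def mean_depth_and_habitat(
    fixes: pd.DataFrame,
    grid: DepthGrid,
    cutoff: float = DEPTH_CUTOFF_M,
    method: str = "linear",
) -> tuple[float, str]:
    """Mean interpolated depth over the fixes and the habitat class.

    Oceanic strictly below the cutoff (default -2200 m); a mean exactly at
    the cutoff is shelf.
    """
    depths = grid.interpolate(fixes["lat"].to_numpy(), fixes["lon"].to_numpy(), method)
    mean_depth = float(np.mean(depths))
    habitat = "oceanic" if mean_depth < cutoff else "shelf"
    return mean_depth, habitat


def boat_association(patch: ARSPatch, track: Track) -> tuple[bool, int]:
    """(associated, n_detections): any positive radar fix inside the patch.

    Interval semantics are boundary-inclusive on both ends; detections just
    outside the interval do not count.
    """
    times = track.times
    inside = (times >= patch.start) & (times <= patch.end)
    n = int(np.sum((track.radar_count > 0) & inside))
    return n > 0, n


def prop_night(patch: ARSPatch, track: Track, mask: DaylightMask) -> float:
    """Duration-weighted fraction of the patch spent at night.

    Each inter-fix interval takes the day/night state of its opening fix.
    """
    idx = patch.fix_indices
    if len(idx) < 2:
        return 0.0
    times = track.times[idx]
    dt = _interval_hours(pd.DatetimeIndex(times))
    night = ~np.asarray(mask.day, dtype=bool)[idx][:-1]
    return float(np.sum(dt[night]) / np.sum(dt))


def find_encounters(track: Track, gap_hours: float = ENCOUNTER_GAP_H) -> list[Encounter]:
    """Maximal series of radar detections with gaps of at most ``gap_hours``.

    A gap strictly longer than ``gap_hours`` between successive detections
    starts a new encounter.
    """
    pos = np.flatnonzero(track.radar_count > 0)
    if pos.size == 0:
        return []
    t = track.times[pos]
    gaps_h = np.diff(t.asi8) / 3.6e12
    breaks = np.flatnonzero(gaps_h > gap_hours)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(pos) - 1]])
    return [
        Encounter(
            bird_id=track.bird_id,
            start=t[s],
            end=t[e],
            n_detections=int(e - s + 1),
        )
        for s, e in zip(starts, ends)
    ]


@dataclass
class TripSummary:
    """Trip-level proportions and counts reported alongside the patch table."""

    bird_id: str
    prop_time_small_ars: float
    prop_time_large_ars: float
    prop_time_with_boat: float
    n_encounters: int
    prop_radar_detections_in_ars: float  # NaN when the trip has no detection
    prop_small_nested: float  # NaN when the trip has no small patch


def describe_patches(
    track: Track,
    patches: list[ARSPatch],
    mask: DaylightMask,
    grid: DepthGrid | None = None,
    *,
    on_water_kmh: float = ON_WATER_KMH,
    depth_cutoff: float = DEPTH_CUTOFF_M,
    nesting_min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Descriptor table: one row per ARS patch.

    Columns mirror the analysis table downstream of detection: response
    (``boat_associated``) and predictors (duration, sinuosity, colony
    distance, depth, on-water and night proportions, nesting), plus
    stratifiers (``scale_class``, ``habitat``).  ``habitat``/``mean_depth``
    are NaN when no bathymetry grid is supplied.
    """
    small = [p for p in patches if p.scale_class == "small"]
    large = [p for p in patches if p.scale_class == "large"]
    nested_small, prop_nested_large = compute_nesting(
        small, large, min_overlap=nesting_min_overlap
    )
    nested_by_id = {id(p): bool(f) for p, f in zip(small, nested_small)}
    propn_by_id = {id(p): float(f) for p, f in zip(large, prop_nested_large)}

    rows = []
    for p in patches:
        idx = p.fix_indices
        if len(idx) < 2:
            log.warning("patch with <2 member fixes skipped (%s)", p.start)
            continue
        sub = track.fixes.iloc[idx]
        assoc, n_det = boat_association(p, track)
        if grid is not None:
            depth, habitat = mean_depth_and_habitat(sub, grid, cutoff=depth_cutoff)
        else:
            depth, habitat = np.nan, None
        colony_d = float(
            np.mean(
                haversine_km(
                    sub["lat"].to_numpy(), sub["lon"].to_numpy(), *track.colony
                )
            )
        )
        if p.scale_class == "small":
            nested_val = float(nested_by_id[id(p)])
            night_val = np.nan
        elif p.scale_class == "large":
            nested_val = propn_by_id[id(p)]
            night_val = prop_night(p, track, mask)
        else:
            nested_val = np.nan
            night_val = prop_night(p, track, mask)
        rows.append(
            {
                "bird_id": p.bird_id,
                "scale_class": p.scale_class,
                "start": p.start,
                "end": p.end,
                "duration_h": p.duration_hours,
                "sinuosity": sinuosity(sub["lat"], sub["lon"]),
                "mean_colony_distance_km": colony_d,
                "mean_depth_m": depth,
                "habitat": habitat,
                "prop_on_water": prop_on_water(sub, v_thresh=on_water_kmh),
                "prop_night": night_val,
                "prop_small_nested": nested_val,
                "boat_associated": bool(assoc),
                "n_radar_detections": n_det,
                "radii_km": ",".join(f"{r:g}" for r in p.radii_km),
            }
        )
    return pd.DataFrame(rows)


def summarize_trip(
    track: Track,
    patches: list[ARSPatch],
    encounters: list[Encounter],
    mask: DaylightMask,
    *,
    nesting_min_overlap: float = 0.5,
) -> TripSummary:
    """Trip-level proportions of time in ARS and of detections inside ARS."""
    trip_h = track.duration_hours
    small = [p for p in patches if p.scale_class == "small"]
    large = [p for p in patches if p.scale_class == "large"]
    t_small = interval_total_hours([p.interval() for p in small])
    t_large = interval_total_hours([p.interval() for p in large])

    times = track.times
    pos = track.radar_count > 0
    n_pos = int(np.sum(pos))
    if n_pos:
        in_ars = np.zeros(len(track), dtype=bool)
        for p in patches:
            in_ars |= (times >= p.start) & (times <= p.end)
        prop_in_ars = float(np.sum(pos & in_ars) / n_pos)
    else:
        prop_in_ars = float("nan")

    # time "with a boat": share of radar scans that heard a ship; the logger
    # scans one minute in five, so scan instants are ~1/5 of the fixes
    prop_with_boat = min(5.0 * n_pos / len(track), 1.0) if len(track) else 0.0

    nested_flags, _ = compute_nesting(small, large, min_overlap=nesting_min_overlap)
    prop_nested = float(np.mean(nested_flags)) if small else float("nan")

    return TripSummary(
        bird_id=track.bird_id,
        prop_time_small_ars=min(t_small / trip_h, 1.0) if trip_h > 0 else 0.0,
        prop_time_large_ars=min(t_large / trip_h, 1.0) if trip_h > 0 else 0.0,
        prop_time_with_boat=prop_with_boat,
        n_encounters=len(encounters),
        prop_radar_detections_in_ars=prop_in_ars,
        prop_small_nested=prop_nested,
    )
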