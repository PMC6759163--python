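"""Core in-memory containers for GPS tracks, resampled paths and ARS patches.

A :class:`Track` is one foraging trip of one bird: an ordered table of GPS
fixes at (nominally) 1-minute intervals, each fix carrying a radar-detection
count from the on-board radar logger (0 when no scan took place or no ship
radar was heard).  All timestamps are UTC; all coordinates are geographic
degrees (WGS-84 treated as a sphere downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TRACK_COLUMNS = ("time", "lat", "lon", "radar_count")


def _as_utc(times) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(times)
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    return idx.tz_convert("UTC")


def make_fixes(
    times, lat, lon, radar_count=None
) -> pd.DataFrame:
    """Assemble a validated fix table (time, lat, lon, radar_count)."""
    idx = _as_utc(times)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if radar_count is None:
        radar_count = np.zeros(len(lat), dtype=int)
    radar_count = np.asarray(radar_count, dtype=int)
    return pd.DataFrame(
        {"time": idx, "lat": lat, "lon": lon, "radar_count": radar_count}
    )


@dataclass
class Track:
    """One foraging trip: ordered fixes plus the colony of departure.

    Parameters
    ----------
    bird_id
        Identifier of the tracked individual.
    fixes
        DataFrame with columns ``time`` (tz-aware UTC), ``lat``, ``lon``,
        ``radar_count``; strictly increasing timestamps, at least 2 rows.
    colony
        ``(lat, lon)`` of the breeding colony, used for distance-to-colony
        descriptors.
    """

    bird_id: str
    fixes: pd.DataFrame
    colony: tuple[float, float]

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.fixes.columns]
        if missing:
            raise ValueError(f"track fixes missing columns {missing}")
        if len(self.fixes) < 2:
            raise ValueError("a track needs at least 2 fixes")
        self.fixes = self.fixes.reset_index(drop=True)
        t = self.fixes["time"]
        if t.dt.tz is None:
            self.fixes["time"] = t.dt.tz_localize("UTC")
        dt = np.diff(pd.DatetimeIndex(self.fixes["time"]).asi8)
        if np.any(dt <= 0):
            raise ValueError("track timestamps must be strictly increasing")
        lat = self.fixes["lat"].to_numpy()
        lon = self.fixes["lon"].to_numpy()
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude outside [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError("longitude outside [-180, 180]")
        if np.any(self.fixes["radar_count"].to_numpy() < 0):
            raise ValueError("radar_count must be non-negative")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.fixes["time"])

    @property
    def lat(self) -> np.ndarray:
        return self.fixes["lat"].to_numpy()

    @property
    def lon(self) -> np.ndarray:
        return self.fixes["lon"].to_numpy()

    @property
    def radar_count(self) -> np.ndarray:
        return self.fixes["radar_count"].to_numpy()

    @property
    def duration_hours(self) -> float:
        span = self.fixes["time"].iloc[-1] - self.fixes["time"].iloc[0]
        return span.total_seconds() / 3600.0


@dataclass
class ResampledPath:
    """A track re-discretised to equal along-path distance steps.

    ``vertices`` has columns ``lat``, ``lon``, ``time`` (UTC), ``dist_km``
    (cumulative along-path distance, exact multiples of ``step_km``) and
    ``leg`` (index of the original fix opening the great-circle leg the
    vertex lies on — the mapping back to the raw track).
    """

    vertices: pd.DataFrame
    step_km: float

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def lat(self) -> np.ndarray:
        return self.vertices["lat"].to_numpy()

    @property
    def lon(self) -> np.ndarray:
        return self.vertices["lon"].to_numpy()

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.vertices["time"])

    @property
    def hours(self) -> np.ndarray:
        """Vertex times as float hours from the first vertex."""
        t = pd.DatetimeIndex(self.vertices["time"]).asi8
        return (t - t[0]) / 3.6e12


@dataclass
class DaylightMask:
    """Per-fix day flag (True = day) at a fixed twilight threshold."""

    day: np.ndarray
    twilight_threshold: float = -6.0

    def __len__(self) -> int:
        return len(self.day)


@dataclass
class FPTSeries:
    """First-passage times (hours) for one radius along a resampled path.

    ``values[i]`` is the time the bird took to traverse the circle of
    ``radius_km`` centred on vertex ``i`` (from the last backward crossing to
    the first forward crossing); NaN where the circle is never exited within
    the track (border effect).
    """

    radius_km: float
    values: np.ndarray
    path: ResampledPath

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class Segmentation:
    """Optimal partition of a series into homogeneous-mean segments.

    ``bounds`` is a list of ``(start, end)`` index pairs (inclusive) covering
    the segmented portion contiguously; ``means`` the per-segment means.
    """

    bounds: list[tuple[int, int]]
    means: np.ndarray
    k: int
    contrasts: np.ndarray  # J(K) for K = 1..Kmax

    def __len__(self) -> int:
        return len(self.bounds)


@dataclass
class ARSPatch:
    """One detected area-restricted-search bout at a given scale class."""

    bird_id: str
    scale_class: str  # "small" | "large" | "very_large"
    start: pd.Timestamp
    end: pd.Timestamp
    radii_km: tuple[float, ...]
    thresholds_h: tuple[float, ...]  # classification threshold per radius
    fix_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("patch end must be after start")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    def interval(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (self.start, self.end)


@dataclass
class Encounter:
    """Maximal run of radar detections separated by gaps of at most 2 h."""

    bird_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    n_detections: int

    def __post_init__(self) -> None:
        if self.n_detections < 1:
            raise ValueError("an encounter has at least one detection")


def interval_union(intervals: Sequence[tuple]) -> list[tuple]:
    """Merge overlapping or touching ``(start, end)`` intervals."""
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: iv[0])
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def interval_total_hours(intervals: Sequence[tuple]) -> float:
    return sum((e - s).total_seconds() / 3600.0 for s, e in interval_union(intervals))
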