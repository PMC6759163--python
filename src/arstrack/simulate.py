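"""Synthetic albatross trips, fishing vessels and radar-logger detections.

The generator produces the data the analysis assumes: 1-minute GPS fixes
from a state-switching correlated random walk over five behavioural states
(commute, large_search, intensive_search, boat_follow, night_rest), vessel
tracks alternating cruising and fishing bouts, and a radar channel that
fires only at the logger's 5-minute duty-cycle instants when a vessel lies
within 5 km.  Every fix carries a ground-truth state label and the distance
to the nearest vessel, so detection and association stages can be scored
against known truth.

Headings evolve as a wrapped (von Mises) random walk with per-state
concentration; speeds are truncated-normal per state.  Intensive search is
reachable only from large-scale search, which builds the nested patch
structure by construction.  Birds within the attraction range of a vessel
steer towards it (albatrosses detect vessels from tens of kilometres) and
may lock into boat-following once inside radar range; at night the bird
rests on the water, drifting slowly.  A single seed fans out to independent
substreams per entity, so adding a vessel never perturbs the bird's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import haversine_km, solar_elevation
from .tracks import Track, make_fixes

STATES = ("commute", "large_search", "intensive_search", "boat_follow", "night_rest")
KM_PER_DEG = 111.19492664455873  # pi * 6371 / 180

DEFAULT_TRANSITION = {
    "commute": {"commute": 0.994, "large_search": 0.006},
    "large_search": {"large_search": 0.982, "commute": 0.006, "intensive_search": 0.012},
    "intensive_search": {"intensive_search": 0.985, "large_search": 0.015},
}
DEFAULT_SPEEDS = {  # km/h: mean, sd
    "commute": (65.0, 10.0),
    "large_search": (45.0, 8.0),
    "intensive_search": (13.0, 4.0),
    "boat_follow": (10.0, 4.0),
    "night_rest": (3.0, 1.5),
}
DEFAULT_KAPPA = {  # von Mises concentration of per-step turning angles
    "commute": 150.0,
    "large_search": 10.0,
    "intensive_search": 0.7,
    "boat_follow": 0.3,
    "night_rest": 0.2,
}
# search is confined: inside a patch the walk is merely persistent, outside
# it steers back towards the patch centre (biased correlated random walk)
DEFAULT_PATCH_RADIUS = {"large_search": 40.0, "intensive_search": 2.0}  # km


@dataclass
class SimConfig:
    """Study conditions for one simulated foraging trip.

    Defaults encode the logger constants (1-min fixes, 5-km radar range,
    one scan per 5 minutes), a colony at Crozet, and movement parameters
    chosen to produce commutes near 65 km/h, multi-hour large-scale search
    bouts containing ~half-hour intensive bouts, slow sinuous loitering
    behind vessels, and slow drift at night.
    """

    trip_duration_h: float = 14.0
    fix_interval_min: float = 1.0
    colony: tuple[float, float] = (-46.35, 51.70)
    start_time: str = "2016-01-15T03:00:00Z"  # ~dawn local time at Crozet
    transition: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in DEFAULT_TRANSITION.items()
    })
    speed_params: dict = field(default_factory=lambda: dict(DEFAULT_SPEEDS))
    turn_kappa: dict = field(default_factory=lambda: dict(DEFAULT_KAPPA))
    n_boats: int = 0
    radar_range_km: float = 5.0
    radar_duty_min: float = 5.0
    boat_attraction_km: float = 30.0
    min_boat_distance_km: float = 40.0
    max_boat_distance_km: float = 250.0
    patch_radius_km: dict = field(default_factory=lambda: dict(DEFAULT_PATCH_RADIUS))
    intensive_drift_kmh: float = 10.0  # natural prey patches progress along fronts
    large_drift_kmh: float = 5.0  # the searched region itself tracks the front
    p_attach: float = 0.3  # per-minute chance to lock on once inside radar range
    p_detach: float = 0.0025  # per-minute chance to leave a vessel in operation
    p_detach_cruising: float = 0.5  # birds quickly abandon fast cruising vessels
    detach_refractory_min: float = 90.0  # no re-attachment/attraction after leaving
    intensive_refractory_min: float = 60.0  # a worked prey patch is left depleted
    intensive_max_min: float = 240.0  # prey patches deplete within a few hours
    speed_ceiling_kmh: float = 95.0
    twilight_deg: float = -6.0
    inject_outliers: bool = False
    n_outliers: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trip_duration_h <= 0:
            raise ValueError("trip_duration_h must be positive")
        if self.fix_interval_min <= 0:
            raise ValueError("fix_interval_min must be positive")
        if self.radar_range_km <= 0:
            raise ValueError("radar_range_km must be positive")
        if self.n_boats < 0:
            raise ValueError("n_boats must be >= 0")
        duty_ratio = self.radar_duty_min / self.fix_interval_min
        if abs(duty_ratio - round(duty_ratio)) > 1e-9:
            raise ValueError("fix_interval_min must divide radar_duty_min")
        for s, row in self.transition.items():
            if s not in STATES:
                raise ValueError(f"transition: unknown state '{s}'")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition: row '{s}' sums to {total}, not 1")
        for s, (mu, sd) in self.speed_params.items():
            if mu < 0 or sd < 0:
                raise ValueError(f"speed_params: negative value for state '{s}'")

    @property
    def n_fixes(self) -> int:
        return int(round(self.trip_duration_h * 60.0 / self.fix_interval_min)) + 1


@dataclass
class BoatTrack:
    """One simulated vessel: fixes plus per-fix activity (cruising/fishing)."""

    boat_id: str
    fixes: pd.DataFrame  # time, lat, lon
    activity: np.ndarray  # "cruising" | "fishing" per fix


@dataclass
class GroundTruth:
    """Per-fix truth: behavioural state and distance to the nearest vessel."""

    state: np.ndarray
    nearest_boat_km: np.ndarray


@dataclass
class SimResult:
    track: Track
    boats: list[BoatTrack]
    truth: GroundTruth

    def __post_init__(self) -> None:
        if len(self.track) != len(self.truth.state):
            raise ValueError("track and truth must have equal length")


def _times(config: SimConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.start_time)
    if start.tz is None:
        start = start.tz_localize("UTC")
    return pd.date_range(
        start, periods=config.n_fixes, freq=pd.Timedelta(minutes=config.fix_interval_min)
    )


def _step(lat, lon, heading_rad, dist_km):
    dlat = dist_km * np.cos(heading_rad) / KM_PER_DEG
    dlon = dist_km * np.sin(heading_rad) / (
        KM_PER_DEG * max(np.cos(np.radians(lat)), 1e-6)
    )
    return lat + dlat, lon + dlon


def _bearing_rad(lat1, lon1, lat2, lon2):
    dlat = (lat2 - lat1) * KM_PER_DEG
    dlon = (lon2 - lon1) * KM_PER_DEG * np.cos(np.radians(lat1))
    return np.arctan2(dlon, dlat)


def simulate_boats(config: SimConfig, rng: np.random.Generator) -> list[BoatTrack]:
    """Simulate ``config.n_boats`` vessels on the trip's time grid.

    Each vessel alternates fast, straight cruising bouts (mean 1.5 h,
    ~18 km/h) and slow fishing bouts (mean 8 h, ~2.5 km/h) worked on a
    confined ground,
    starting at a uniform-random position within ``max_boat_distance_km``
    of the colony.  Deterministic given the generator state.
    """
    times = _times(config)
    n = len(times)
    dt_h = config.fix_interval_min / 60.0
    boats = []
    streams = rng.spawn(config.n_boats) if config.n_boats else []
    for b, sub in enumerate(streams):
        # area-uniform in an annulus around the colony, matching the
        # radial band where the birds run their search bouts
        r = np.sqrt(
            sub.uniform(config.min_boat_distance_km**2, config.max_boat_distance_km**2)
        )
        th = sub.uniform(0, 2 * np.pi)
        lat = config.colony[0] + r * np.cos(th) / KM_PER_DEG
        lon = config.colony[1] + r * np.sin(th) / (
            KM_PER_DEG * np.cos(np.radians(config.colony[0]))
        )
        heading = sub.uniform(0, 2 * np.pi)
        fishing = sub.uniform() < 0.6
        bout_left = sub.exponential(480.0 if fishing else 90.0)  # minutes
        ground = (lat, lon)  # fishing bouts work a confined ground
        lats = np.empty(n)
        lons = np.empty(n)
        act = np.empty(n, dtype=object)
        for i in range(n):
            lats[i], lons[i] = lat, lon
            act[i] = "fishing" if fishing else "cruising"
            bout_left -= config.fix_interval_min
            if bout_left <= 0:
                fishing = not fishing
                bout_left = sub.exponential(480.0 if fishing else 90.0)
                if fishing:
                    ground = (lat, lon)
            if fishing:
                speed = max(sub.normal(2.5, 1.0), 0.0)
                if haversine_km(lat, lon, *ground) > 2.0:
                    heading = _bearing_rad(lat, lon, *ground) + sub.vonmises(0.0, 2.0)
                else:
                    heading += sub.vonmises(0.0, 1.0)
            else:
                speed = max(sub.normal(18.0, 3.0), 0.0)
                heading += sub.vonmises(0.0, 50.0)
            lat, lon = _step(lat, lon, heading, speed * dt_h)
        boats.append(
            BoatTrack(
                boat_id=f"boat{b}",
                fixes=make_fixes(times, lats, lons).drop(columns="radar_count"),
                activity=act,
            )
        )
    return boats


def simulate_trip(
    config: SimConfig, boats: list[BoatTrack], rng: np.random.Generator
) -> SimResult:
    """Simulate one bird trip among the given vessels.

    The bird leaves the colony commuting; enters boat_follow only from
    within radar range; rests on the water when the sun is more than 6
    degrees below the horizon; radar counts are emitted only at duty-cycle
    instants with a vessel inside radar range.
    """
    times = _times(config)
    n = len(times)
    dt_h = config.fix_interval_min / 60.0
    duty = int(round(config.radar_duty_min / config.fix_interval_min))

    # align vessels onto the trip grid by timestamp; instants a vessel does
    # not cover become NaN (a vessel disjoint in time yields no detections)
    if boats:
        boat_lat = np.full((len(boats), n), np.nan)
        boat_lon = np.full((len(boats), n), np.nan)
        boat_fishing = np.zeros((len(boats), n), dtype=bool)
        for bi, b in enumerate(boats):
            bt = pd.DatetimeIndex(b.fixes["time"])
            pos = times.get_indexer(bt)
            ok = pos >= 0
            boat_lat[bi, pos[ok]] = b.fixes["lat"].to_numpy()[ok]
            boat_lon[bi, pos[ok]] = b.fixes["lon"].to_numpy()[ok]
            boat_fishing[bi, pos[ok]] = np.asarray(b.activity)[ok] == "fishing"
    else:
        boat_lat = boat_lon = None

    lat, lon = config.colony
    heading = rng.uniform(0, 2 * np.pi)
    state = "commute"
    saved_state = "commute"
    refractory = 0.0  # minutes left ignoring vessels after leaving one
    prev_state = "commute"
    patch_center: tuple[float, float] | None = None
    commute_bearing = heading
    drift_bearing = 0.0
    drift_speed = 0.0
    follow_target = -1  # vessel index the bird is attending
    post_attendance = False
    int_refractory = 0.0
    int_run_min = 0.0
    # oceanographic fronts have a consistent orientation within a trip's
    # region; successive natural search bouts progress the same way
    front_bearing = rng.uniform(0, 2 * np.pi)

    lats = np.empty(n)
    lons = np.empty(n)
    states = np.empty(n, dtype=object)
    nearest = np.full(n, np.inf)
    radar = np.zeros(n, dtype=int)

    trans_states = {s: list(row.keys()) for s, row in config.transition.items()}
    trans_probs = {s: np.array(list(row.values())) for s, row in config.transition.items()}

    # solar elevation along the trip is evaluated at the current position,
    # which is only known step by step; the sun moves slowly enough that the
    # per-step evaluation is exact, just not vectorisable
    for i in range(n):
        lats[i], lons[i] = lat, lon

        if boats:
            with np.errstate(invalid="ignore"):
                d = haversine_km(lat, lon, boat_lat[:, i], boat_lon[:, i])
            if np.all(np.isnan(d)):
                j_near = -1
            else:
                j_near = int(np.nanargmin(d))
                nearest[i] = float(d[j_near])
            # birds single out vessels in operation (offal and baits)
            d_fish = np.where(boat_fishing[:, i] & ~np.isnan(d), d, np.inf)
            j_fish = int(np.argmin(d_fish)) if np.isfinite(d_fish).any() else -1
            fish_dist = float(d_fish[j_fish]) if j_fish >= 0 else np.inf
        else:
            j_near = -1
            j_fish = -1
            fish_dist = np.inf

        night = solar_elevation(times[i], lat, lon) < config.twilight_deg
        if night:
            if state != "night_rest":
                saved_state = state if state != "boat_follow" else "large_search"
            state = "night_rest"
        elif state == "night_rest":
            state = saved_state

        if state != "night_rest":
            if state == "boat_follow":
                p_leave = (
                    config.p_detach
                    if follow_target >= 0 and boat_fishing[follow_target, i]
                    else config.p_detach_cruising
                )
                follow_dist = (
                    float(d[follow_target]) if follow_target >= 0 else np.inf
                )
                if (
                    not np.isfinite(follow_dist)
                    or follow_dist > 1.5 * config.radar_range_km
                    or rng.uniform() < p_leave
                ):
                    # birds leaving a vessel keep searching the offal trail
                    # around it before moving on
                    state = "intensive_search"
                    follow_target = -1
                    refractory = config.detach_refractory_min
                    post_attendance = True
            elif (
                boats
                and refractory <= 0
                and fish_dist <= config.radar_range_km
                and rng.uniform() < config.p_attach
            ):
                state = "boat_follow"
                follow_target = j_fish
            else:
                new_state = str(rng.choice(trans_states[state], p=trans_probs[state]))
                if new_state == "intensive_search" and state != "intensive_search":
                    if int_refractory > 0:
                        new_state = state  # depleted patch: keep searching widely
                if (
                    state == "intensive_search"
                    and new_state == "intensive_search"
                    and int_run_min >= config.intensive_max_min
                ):
                    new_state = "large_search"  # the patch is exhausted
                if state == "intensive_search" and new_state != "intensive_search":
                    int_refractory = config.intensive_refractory_min
                state = new_state

        states[i] = state
        refractory = max(0.0, refractory - config.fix_interval_min)
        int_refractory = max(0.0, int_refractory - config.fix_interval_min)
        int_run_min = (
            int_run_min + config.fix_interval_min
            if state == "intensive_search"
            else 0.0
        )

        if i % duty == 0 and boats:
            radar[i] = int(np.sum(d <= config.radar_range_km))

        # a fresh search bout anchors a patch centre at the entry position;
        # a fresh commute bout draws a goal bearing the bird then holds
        if state in config.patch_radius_km and state != prev_state:
            patch_center = (lat, lon)
            if state == "intensive_search":
                # natural fine-scale search tracks a drifting front rather
                # than a fixed point, so bouts progress while staying tight;
                # post-attendance search works the local offal trail instead
                drift_bearing = front_bearing + rng.normal(0.0, 0.5)
                if post_attendance:
                    drift_speed = 0.0
                    post_attendance = False
                else:
                    drift_speed = max(rng.normal(config.intensive_drift_kmh, 2.0), 0.0)
        if state == "intensive_search" and patch_center is not None:
            patch_center = _step(*patch_center, drift_bearing, drift_speed * dt_h)
        elif state == "large_search" and patch_center is not None:
            patch_center = _step(
                *patch_center, front_bearing, config.large_drift_kmh * dt_h
            )
        if state == "commute" and prev_state != "commute":
            commute_bearing = heading if prev_state == "night_rest" else rng.uniform(0, 2 * np.pi)

        # propagate to the next fix
        mu, sd = config.speed_params[state]
        speed = float(np.clip(rng.normal(mu, sd), 0.0, config.speed_ceiling_kmh))
        if state == "boat_follow" and follow_target >= 0:
            tlat, tlon = boat_lat[follow_target, i], boat_lon[follow_target, i]
            fdist = float(d[follow_target])
            to_boat = _bearing_rad(lat, lon, tlat, tlon)
            kappa = 0.5 if fdist < 2.0 else 4.0
            heading = to_boat + rng.vonmises(0.0, kappa)
            if fdist > 3.0:
                speed = max(speed, 12.0)
        elif (
            boats
            and not night
            and refractory <= 0
            and state in ("commute", "large_search")
            and fish_dist <= config.boat_attraction_km
            and fish_dist > config.radar_range_km
        ):
            to_boat = _bearing_rad(lat, lon, boat_lat[j_fish, i], boat_lon[j_fish, i])
            heading = to_boat + rng.vonmises(0.0, 8.0)
        elif (
            state in config.patch_radius_km
            and patch_center is not None
            and haversine_km(lat, lon, *patch_center) > config.patch_radius_km[state]
        ):
            to_center = _bearing_rad(lat, lon, *patch_center)
            heading = to_center + rng.vonmises(0.0, 2.0)
        elif state == "commute":
            # wobble around the bout's goal bearing: no heading drift, so
            # commutes stay straight over hours (goal-directed flight)
            heading = commute_bearing + rng.vonmises(0.0, config.turn_kappa["commute"])
        else:
            heading = heading + rng.vonmises(0.0, config.turn_kappa[state])
        prev_state = state
        lat, lon = _step(lat, lon, heading, speed * dt_h)

    nearest[~np.isfinite(nearest)] = np.inf

    fixes = make_fixes(times, lats, lons, radar)
    if config.inject_outliers and config.n_outliers > 0:
        idx = rng.choice(np.arange(1, n - 1), size=min(config.n_outliers, n - 2), replace=False)
        fixes.loc[idx, "lat"] = np.clip(fixes.loc[idx, "lat"] + 0.5, -90, 90)

    track = Track(bird_id=f"bird{config.seed}", fixes=fixes, colony=config.colony)
    truth = GroundTruth(state=states, nearest_boat_km=nearest)
    return SimResult(track=track, boats=boats, truth=truth)


def simulate(config: SimConfig) -> SimResult:
    """Boats + trip from the single seed, with per-entity substreams."""
    root = np.random.SeedSequence(config.seed)
    boat_seq, bird_seq = root.spawn(2)
    boats = simulate_boats(config, np.random.Generator(np.random.PCG64(boat_seq)))
    return simulate_trip(config, boats, np.random.Generator(np.random.PCG64(bird_seq)))


def truth_intervals(
    result: SimResult, states: tuple[str, ...]
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Maximal time intervals whose fixes are all in the given states."""
    member = np.isin(result.truth.state, states)
    times = result.track.times
    intervals = []
    i, n = 0, len(member)
    while i < n:
        if not member[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and member[j + 1]:
            j += 1
        intervals.append((times[i], times[j]))
        i = j + 1
    return intervals


def small_truth_intervals(result: SimResult, min_duration_h: float = 0.5):
    """Truth bouts expected to surface as small-scale ARS (intensive search
    or boat-following), longer than ``min_duration_h``."""
    ivs = truth_intervals(result, ("intensive_search", "boat_follow"))
    return [iv for iv in ivs if (iv[1] - iv[0]).total_seconds() / 3600.0 >= min_duration_h]


def large_truth_intervals(result: SimResult, min_duration_h: float = 2.0):
    """Truth bouts expected to surface as large-scale ARS (large-scale search
    with any nested intensive or boat-following bouts inside)."""
    ivs = truth_intervals(
        result, ("large_search", "intensive_search", "boat_follow")
    )
    return [iv for iv in ivs if (iv[1] - iv[0]).total_seconds() / 3600.0 >= min_duration_h]


def write_truth_csv(result: SimResult, path) -> None:
    """Ground-truth CSV: fix index, state, nearest_boat_km."""
    nb = result.truth.nearest_boat_km
    df = pd.DataFrame(
        {
            "fix": np.arange(len(result.track)),
            "state": result.truth.state,
            "nearest_boat_km": np.where(np.isfinite(nb), nb, np.nan),
        }
    )
    df.to_csv(path, index=False)


def vary_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of the config with a different seed (bird_id follows the seed)."""
    return replace(config, seed=seed)
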