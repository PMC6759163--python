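import numpy as np
import pandas as pd
import pytest

from arstrack import SimConfig, Track, make_fixes, simulate

KM_PER_DEG = np.pi * 6371.0 / 180.0


def track_from_km(
    xy_km,
    dt_min=1.0,
    lat0=-46.0,
    lon0=51.0,
    t0="2016-01-15T08:00:00Z",
    radar=None,
    bird_id="b1",
):
    """Build a Track from local planar offsets in km (east, north)."""
    xy = np.asarray(xy_km, dtype=float)
    lat = lat0 + xy[:, 1] / KM_PER_DEG
    lon = lon0 + xy[:, 0] / (KM_PER_DEG * np.cos(np.radians(lat0)))
    times = pd.date_range(t0, periods=len(xy), freq=pd.Timedelta(minutes=dt_min))
    return Track(bird_id, make_fixes(times, lat, lon, radar), colony=(lat0, lon0))


def equator_track(n_fixes, speed_kmh, dt_min=1.0, t0="2016-03-20T06:00:00Z"):
    """Straight eastward track along the equator at constant speed.

    On the equator the path is a great circle and haversine distances along
    it are exact, so closed-form FPT checks hold to machine precision.
    """
    step_km = speed_kmh * dt_min / 60.0
    lon = np.arange(n_fixes) * step_km / KM_PER_DEG
    lat = np.zeros(n_fixes)
    times = pd.date_range(t0, periods=n_fixes, freq=pd.Timedelta(minutes=dt_min))
    return Track("eq", make_fixes(times, lat, lon), colony=(0.0, 0.0))


@pytest.fixture(scope="session")
def simulated_trip():
    """One 14-h trip among vessels, with ground truth (session-cached)."""
    return simulate(SimConfig(trip_duration_h=14.0, n_boats=12, seed=8))


@pytest.fixture(scope="session")
def boatless_trip():
    return simulate(SimConfig(trip_duration_h=14.0, n_boats=0, seed=5))
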