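import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arstrack import (
    SimConfig,
    daylight_mask,
    filter_speed,
    haversine_km,
    resample_equal_distance,
    simulate,
    solar_elevation,
    split_daylight_subtracks,
)
from arstrack.tracks import DaylightMask

from conftest import equator_track, track_from_km
from solar_oracle import solar_elevation_noaa


class TestHaversine:
    def test_identical_points_are_zero(self):
        assert haversine_km(-46.35, 51.70, -46.35, 51.70) == 0.0

    def test_one_degree_of_latitude(self):
        # pi * 6371 / 180 = 111.19 km per degree of latitude
        d = haversine_km(-46.35, 51.70, -45.35, 51.70)
        assert d == pytest.approx(111.19, abs=0.01)

    @given(st.tuples(
        st.floats(-89, 89), st.floats(-179, 179),
        st.floats(-89, 89), st.floats(-179, 179),
    ))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_nonnegativity(self, pts):
        la1, lo1, la2, lo2 = pts
        d1 = haversine_km(la1, lo1, la2, lo2)
        d2 = haversine_km(la2, lo2, la1, lo1)
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert d1 >= 0


class TestSpeedFilter:
    def test_clean_track_unchanged(self):
        tr = equator_track(30, speed_kmh=60.0)
        out = filter_speed(tr, vmax=100.0)
        assert len(out) == len(tr)
        pd.testing.assert_frame_equal(out.fixes, tr.fixes)

    def test_single_spike_removed(self):
        # fix 2 jumps ~8.3 km in 1 min (500 km/h) both ways; 1 -> 3 is slow
        xy = [(0.0, 0.0), (0.3, 0.0), (8.3, 0.0), (0.6, 0.0)]
        tr = track_from_km(xy)
        out = filter_speed(tr, vmax=100.0)
        assert len(out) == 3
        assert out.fixes["lon"].iloc[2] == tr.fixes["lon"].iloc[3]

    def test_infinite_threshold_is_noop(self):
        xy = [(0.0, 0.0), (0.3, 0.0), (8.3, 0.0), (0.6, 0.0)]
        tr = track_from_km(xy)
        out = filter_speed(tr, vmax=np.inf)
        assert len(out) == len(tr)

    def test_idempotent_on_simulated_outliers(self):
        res = simulate(SimConfig(trip_duration_h=6, inject_outliers=True, seed=11))
        once = filter_speed(res.track)
        twice = filter_speed(once)
        pd.testing.assert_frame_equal(once.fixes, twice.fixes)
        assert len(once) < len(res.track)

    def test_unusable_track_raises(self):
        xy = [(0.0, 0.0), (50.0, 0.0), (0.0, 50.0)]  # every move too fast
        with pytest.raises(ValueError, match="unusable"):
            filter_speed(track_from_km(xy), vmax=100.0)


class TestResampling:
    def test_uniform_leg_vertex_count_and_times(self):
        # 10 km at 60 km/h -> 11 vertices including both ends, 1 min apart
        tr = equator_track(11, speed_kmh=60.0)  # 1-km steps
        path = resample_equal_distance(tr, step_km=1.0)
        assert len(path) == 11
        dt = np.diff(path.times.asi8) / 60e9
        assert np.allclose(dt, 1.0, atol=1e-6)

    def test_trailing_partial_step_dropped(self):
        xy = np.column_stack([np.linspace(0, 10.5, 22), np.zeros(22)])
        path = resample_equal_distance(track_from_km(xy), step_km=1.0)
        assert len(path) == 11
        assert path.vertices["dist_km"].iloc[-1] == pytest.approx(10.0)

    def test_too_short_path_raises(self):
        xy = [(0.0, 0.0), (0.2, 0.0)]
        with pytest.raises(ValueError, match="short"):
            resample_equal_distance(track_from_km(xy), step_km=1.0)

    def test_vertex_distances_recompute_with_haversine(self, boatless_trip):
        """Along-path distance of vertex i (cumulated to the bracketing fix
        plus the final great-circle chunk) equals i*step within 1e-6 km."""
        track = filter_speed(boatless_trip.track)
        path = resample_equal_distance(track, step_km=1.0)
        lat, lon = track.lat, track.lon
        leg = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        cum = np.concatenate([[0.0], np.cumsum(leg)])
        j = path.vertices["leg"].to_numpy()
        partial = haversine_km(lat[j], lon[j], path.lat, path.lon)
        recomputed = cum[j] + partial
        assert np.allclose(recomputed, path.vertices["dist_km"], atol=1e-6)

    def test_vertex_times_within_bracketing_fixes(self, boatless_trip):
        track = filter_speed(boatless_trip.track)
        path = resample_equal_distance(track, step_km=1.0)
        j = path.vertices["leg"].to_numpy()
        t = path.times.asi8
        t_fix = track.times.asi8
        assert np.all(t >= t_fix[j])
        assert np.all(t <= t_fix[j + 1])


class TestSolarGeometry:
    def test_equinox_noon_near_zenith(self):
        # local solar noon on the equator at the 2016 March equinox
        elev = solar_elevation("2016-03-20T12:07:00Z", 0.0, 0.0)
        assert elev == pytest.approx(90.0, abs=1.0)

    def test_equinox_midnight_near_nadir(self):
        elev = solar_elevation("2016-03-20T00:07:00Z", 0.0, 0.0)
        assert elev == pytest.approx(-90.0, abs=1.0)

    def test_matches_noaa_oracle_on_random_space_time(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            lat = rng.uniform(-65, 65)
            lon = rng.uniform(-180, 180)
            t = pd.Timestamp("2016-01-01", tz="UTC") + pd.Timedelta(
                seconds=float(rng.uniform(0, 3 * 365 * 86400))
            )
            ours = solar_elevation(t, lat, lon)
            oracle = solar_elevation_noaa(t, lat, lon)
            assert ours == pytest.approx(oracle, abs=0.2)

    def test_twilight_crossing_within_two_minutes_of_oracle(self):
        # scan a summer evening at Crozet in 30-s steps for the -6 deg crossing
        lat, lon = -46.35, 51.70
        times = pd.date_range(
            "2016-01-15T16:00:00Z", "2016-01-15T20:00:00Z", freq="30s"
        )
        ours = np.array([solar_elevation(t, lat, lon) for t in times])
        oracle = np.array([solar_elevation_noaa(t, lat, lon) for t in times])
        i_ours = int(np.argmax(ours < -6.0))
        i_oracle = int(np.argmax(oracle < -6.0))
        assert i_ours > 0 and i_oracle > 0
        assert abs(times[i_ours] - times[i_oracle]) <= pd.Timedelta(minutes=2)


class TestDaylight:
    def test_sun_always_up_all_day(self):
        tr = equator_track(60, speed_kmh=60.0, t0="2016-03-20T10:00:00Z")
        mask = daylight_mask(tr)
        assert mask.day.all()

    def test_impossible_threshold_all_night(self):
        tr = equator_track(60, speed_kmh=60.0)
        mask = daylight_mask(tr, threshold=90.0)
        assert not mask.day.any()

    def test_day_night_day_partition(self):
        tr = equator_track(20, speed_kmh=60.0)
        mask = DaylightMask(day=np.array([True] * 8 + [False] * 5 + [True] * 7))
        subs = split_daylight_subtracks(tr, mask)
        assert len(subs) == 2
        assert sum(len(s) for s in subs) == 15

    def test_all_night_yields_nothing(self):
        tr = equator_track(20, speed_kmh=60.0)
        mask = DaylightMask(day=np.zeros(20, dtype=bool))
        assert split_daylight_subtracks(tr, mask) == []
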