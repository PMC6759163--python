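import numpy as np
import pandas as pd
import pytest

from arstrack import (
    SimConfig,
    haversine_km,
    simulate,
    simulate_boats,
    simulate_trip,
    truth_intervals,
)
from arstrack.preprocess import step_speeds_kmh
from arstrack.simulate import STATES


class TestConfigValidation:
    def test_bad_transition_row_named(self):
        with pytest.raises(ValueError, match="transition"):
            SimConfig(transition={"commute": {"commute": 0.9}})

    def test_negative_speed_named(self):
        with pytest.raises(ValueError, match="speed_params"):
            SimConfig(speed_params={"commute": (-5.0, 1.0)})

    def test_duty_cycle_divisibility(self):
        with pytest.raises(ValueError, match="divide"):
            SimConfig(fix_interval_min=3.0, radar_duty_min=5.0)

    def test_negative_boats_rejected(self):
        with pytest.raises(ValueError, match="n_boats"):
            SimConfig(n_boats=-1)


class TestBoats:
    def test_zero_boats_empty_list(self):
        cfg = SimConfig(n_boats=0)
        assert simulate_boats(cfg, np.random.default_rng(0)) == []

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_boats=3, trip_duration_h=4)
        a = simulate_boats(cfg, np.random.default_rng(9))
        b = simulate_boats(cfg, np.random.default_rng(9))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.fixes, y.fixes)
            assert (x.activity == y.activity).all()

    def test_fishing_slower_than_cruising(self):
        """Empirical bout speeds: fishing loiters, cruising transits."""
        for seed in range(10):
            cfg = SimConfig(n_boats=2, trip_duration_h=24, seed=seed)
            boats = simulate_boats(cfg, np.random.default_rng(seed))
            for b in boats:
                lat = b.fixes["lat"].to_numpy()
                lon = b.fixes["lon"].to_numpy()
                sp = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) * 60.0
                act = b.activity[:-1]
                fishing, cruising = sp[act == "fishing"], sp[act == "cruising"]
                if len(fishing) > 30 and len(cruising) > 30:
                    assert fishing.mean() < cruising.mean()


class TestTrip:
    def test_fix_count(self):
        cfg = SimConfig(trip_duration_h=2.0, fix_interval_min=1.0)
        res = simulate(cfg)
        assert len(res.track) == 121

    def test_no_boats_no_detections_no_following(self):
        res = simulate(SimConfig(trip_duration_h=6.0, n_boats=0, seed=4))
        assert (res.track.radar_count == 0).all()
        assert "boat_follow" not in set(res.truth.state)

    def test_bitwise_determinism(self):
        cfg = SimConfig(trip_duration_h=6.0, n_boats=4, seed=21)
        a = simulate(cfg)
        b = simulate(cfg)
        pd.testing.assert_frame_equal(a.track.fixes, b.track.fixes)
        assert (a.truth.state == b.truth.state).all()
        assert np.array_equal(a.truth.nearest_boat_km, b.truth.nearest_boat_km)

    def test_radar_consistency_over_seeds(self):
        """Positive detection count implies a vessel within 5 km, always."""
        for seed in range(20):
            res = simulate(SimConfig(trip_duration_h=10.0, n_boats=2, seed=seed))
            pos = res.track.radar_count > 0
            if pos.any():
                assert np.all(res.truth.nearest_boat_km[pos] <= 5.0 + 1e-9)

    def test_radar_fires_only_on_duty_instants(self):
        res = simulate(SimConfig(trip_duration_h=10.0, n_boats=8, seed=6))
        pos = np.flatnonzero(res.track.radar_count > 0)
        assert np.all(pos % 5 == 0)

    def test_speed_ceiling_respected(self):
        res = simulate(SimConfig(trip_duration_h=10.0, seed=8))
        assert step_speeds_kmh(res.track).max() <= 100.0

    def test_outlier_injection_creates_fast_fixes(self):
        res = simulate(SimConfig(trip_duration_h=6.0, inject_outliers=True, seed=8))
        assert step_speeds_kmh(res.track).max() > 100.0

    def test_states_from_known_palette(self):
        res = simulate(SimConfig(trip_duration_h=8.0, n_boats=2, seed=1))
        assert set(res.truth.state) <= set(STATES)

    def test_night_rest_is_slow_and_present_on_long_trips(self):
        res = simulate(SimConfig(trip_duration_h=38.0, seed=2))
        night = res.truth.state == "night_rest"
        assert night.sum() > 120  # the trip spans a night
        sp = step_speeds_kmh(res.track)
        night_sp = sp[night[:-1]]
        assert np.mean(night_sp < 10.0) > 0.9

    def test_disjoint_boat_times_yield_no_detections(self):
        cfg = SimConfig(trip_duration_h=4.0, n_boats=2, seed=5)
        shifted = SimConfig(
            trip_duration_h=4.0, n_boats=2, seed=5,
            start_time="2015-06-01T03:00:00Z",
        )
        boats = simulate_boats(shifted, np.random.default_rng(5))
        res = simulate_trip(cfg, boats, np.random.default_rng(5))
        assert (res.track.radar_count == 0).all()
        assert "boat_follow" not in set(res.truth.state)


class TestNesting:
    def test_intensive_bouts_lie_inside_large_bouts(self):
        """Fine-scale search is entered from wide-scale search only, so
        intensive bout midpoints fall inside large-search runs."""
        n_nested = n_total = 0
        for seed in range(10):
            res = simulate(SimConfig(trip_duration_h=14.0, seed=seed))
            large = truth_intervals(
                res, ("large_search", "intensive_search", "boat_follow")
            )
            for s, e in truth_intervals(res, ("intensive_search",)):
                mid = s + (e - s) / 2
                n_total += 1
                n_nested += any(a <= mid <= b for a, b in large)
        assert n_total > 10
        assert n_nested / n_total >= 0.9
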