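import numpy as np
import pandas as pd
import pytest

from arstrack import (
    ARSPatch,
    Track,
    analyse_trip,
    boat_association,
    find_encounters,
    make_fixes,
    mean_depth_and_habitat,
    prop_on_water,
    sinuosity,
    summarize_trip,
    uniform_bathymetry,
)
from arstrack.descriptors import TripSummary
from arstrack.preprocess import daylight_mask

from conftest import track_from_km


class TestSinuosity:
    def test_straight_path_zero(self):
        lat = np.zeros(10)
        lon = np.linspace(0, 0.1, 10)
        assert sinuosity(lat, lon) == pytest.approx(0.0, abs=1e-9)

    def test_closed_loop_one(self):
        lat = np.array([0.0, 0.01, 0.01, 0.0, 0.0])
        lon = np.array([0.0, 0.0, 0.01, 0.01, 0.0])
        assert sinuosity(lat, lon) == pytest.approx(1.0, abs=1e-9)

    def test_right_angle_path(self):
        # two 1-km legs at a right angle: 1 - sqrt(2)/2 at small scale
        lat0 = 0.0
        km = 1.0 / 111.19492664455873
        lat = np.array([0.0, 0.0, km])
        lon = np.array([0.0, km, km])
        assert sinuosity(lat, lon) == pytest.approx(1 - np.sqrt(2) / 2, abs=1e-4)

    def test_stationary_defined_as_zero(self):
        lat = np.zeros(5)
        lon = np.zeros(5)
        assert sinuosity(lat, lon) == 0.0


class TestOnWater:
    def _fixes(self, speeds_kmh, dt_min=1.0):
        km = np.concatenate([[0.0], np.cumsum(np.array(speeds_kmh) * dt_min / 60.0)])
        xy = np.column_stack([km, np.zeros(len(km))])
        return track_from_km(xy, dt_min=dt_min).fixes

    def test_all_fast_zero(self):
        assert prop_on_water(self._fixes([50] * 10)) == 0.0

    def test_all_slow_one(self):
        assert prop_on_water(self._fixes([2] * 10)) == 1.0

    def test_half_duration_below_threshold(self):
        assert prop_on_water(self._fixes([2] * 5 + [50] * 5)) == pytest.approx(0.5)


class TestDepthHabitat:
    def _fixes(self):
        return track_from_km([(0, 0), (1, 0), (2, 0)]).fixes

    def test_deep_water_is_oceanic(self):
        grid = uniform_bathymetry(-3968.7)
        depth, habitat = mean_depth_and_habitat(self._fixes(), grid)
        assert habitat == "oceanic"
        assert depth == pytest.approx(-3968.7)

    def test_shallow_water_is_shelf(self):
        grid = uniform_bathymetry(-1185.9)
        _, habitat = mean_depth_and_habitat(self._fixes(), grid)
        assert habitat == "shelf"

    def test_exact_cutoff_is_shelf(self):
        grid = uniform_bathymetry(-2200.0)
        _, habitat = mean_depth_and_habitat(self._fixes(), grid)
        assert habitat == "shelf"

    def test_fix_outside_grid_named(self):
        grid = uniform_bathymetry(-1000.0, lat_range=(-50, -40), lon_range=(40, 60))
        fixes = make_fixes(
            pd.date_range("2016-01-15", periods=2, freq="1min"),
            [10.0, 10.0], [0.0, 0.1],
        )
        with pytest.raises(ValueError, match="outside"):
            mean_depth_and_habitat(fixes, grid)


class TestBoatAssociation:
    def _track_with_radar(self, radar):
        xy = [(i * 0.5, 0.0) for i in range(len(radar))]
        return track_from_km(xy, radar=radar)

    def _patch(self, track, i0, i1):
        return ARSPatch(
            bird_id=track.bird_id,
            scale_class="small",
            start=track.times[i0],
            end=track.times[i1],
            radii_km=(2.0,),
            thresholds_h=(1.0,),
            fix_indices=np.arange(i0, i1 + 1),
        )

    def test_no_detection_not_associated(self):
        tr = self._track_with_radar([0] * 10)
        assert boat_association(self._patch(tr, 2, 7), tr) == (False, 0)

    def test_single_detection_associated(self):
        tr = self._track_with_radar([0, 0, 0, 1, 0, 0, 0, 0, 0, 0])
        assert boat_association(self._patch(tr, 2, 7), tr) == (True, 1)

    def test_detection_outside_interval_ignored(self):
        tr = self._track_with_radar([1, 0, 0, 0, 0, 0, 0, 0, 0, 2])
        assert boat_association(self._patch(tr, 2, 7), tr) == (False, 0)


class TestEncounters:
    def _track(self, detection_minutes, n=200):
        radar = np.zeros(n, dtype=int)
        for m in detection_minutes:
            radar[m] = 1
        xy = [(i * 0.5, 0.0) for i in range(n)]
        return track_from_km(xy, radar=radar)

    def test_gap_119_minutes_joins(self):
        enc = find_encounters(self._track([0, 119]))
        assert len(enc) == 1
        assert enc[0].n_detections == 2

    def test_gap_121_minutes_splits(self):
        enc = find_encounters(self._track([0, 121]))
        assert len(enc) == 2

    def test_no_detections_empty(self):
        assert find_encounters(self._track([])) == []

    def test_every_detection_in_exactly_one_encounter(self):
        mins = [0, 30, 60, 185, 190]
        enc = find_encounters(self._track(mins))
        assert sum(e.n_detections for e in enc) == len(mins)

    def test_count_invariant_under_time_reversal(self):
        mins = [0, 30, 60, 185, 190]
        tr = self._track(mins)
        rev_mins = [199 - m for m in mins]
        tr_rev = self._track(rev_mins)
        assert len(find_encounters(tr)) == len(find_encounters(tr_rev))


class TestTripSummary:
    def test_zero_patches_zero_proportions(self):
        tr = track_from_km([(i, 0.0) for i in range(30)])
        mask = daylight_mask(tr)
        s = summarize_trip(tr, [], [], mask)
        assert isinstance(s, TripSummary)
        assert s.prop_time_small_ars == 0.0
        assert s.prop_time_large_ars == 0.0
        assert np.isnan(s.prop_radar_detections_in_ars)

    def test_radar_detections_fall_mostly_in_ars(self, simulated_trip):
        tr = analyse_trip(simulated_trip.track)
        s = tr.summary
        assert 0.0 <= s.prop_radar_detections_in_ars <= 1.0
        assert s.n_encounters >= 1
        assert 0.0 < s.prop_time_with_boat <= 1.0

    def test_descriptor_table_row_per_patch(self, simulated_trip):
        tr = analyse_trip(simulated_trip.track)
        assert len(tr.descriptors) == len(tr.patches)
        assert tr.descriptors["sinuosity"].notna().all()
        small = tr.descriptors[tr.descriptors["scale_class"] == "small"]
        assert small["prop_small_nested"].isin([0.0, 1.0]).all()
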