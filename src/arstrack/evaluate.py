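"""Scoring detected ARS patches against simulator ground truth.

The simulator labels every fix with its generating behavioural state, so
detection quality can be expressed as interval-level sensitivity (which
true search bouts were recovered) and precision (which detected patches
overlap real search behaviour).

Conventions
-----------
* A truth bout counts as *recovered* when at least half of its duration is
  covered by the union of detected patches of the matching scale group.
* A detected patch counts as a *true positive* when it overlaps any true
  search interval of the matching scale at all (FPT smears every detected
  interval outward by roughly one radius of path, so demanding containment
  would penalise the method for its own scale).
* Sensitivity is scored only on bouts that the method can physically see:
  bouts whose interval is clear of the track ends by a border margin (FPT
  is undefined near the ends, over a width proportional to the radius).
  Precision is scored against all true search intervals with no duration
  floor — firing on a short real bout is not a false alarm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimResult, truth_intervals
from .tracks import ARSPatch, interval_union

# states whose bouts should surface at each detection scale
SMALL_STATES = ("intensive_search", "boat_follow")
LARGE_STATES = ("large_search", "intensive_search", "boat_follow")

# a bout shorter than this cannot register at the scale's smallest radius
MIN_TRUTH_H = {"small": 0.5, "large": 2.0}
BORDER_MARGIN_H = {"small": 0.25, "large": 1.5}


def overlap_fraction(interval, intervals) -> float:
    """Fraction of ``interval`` covered by the union of ``intervals``."""
    s, e = interval
    total = (e - s).total_seconds()
    if total <= 0:
        return 0.0
    covered = 0.0
    for s2, e2 in interval_union(intervals):
        lo, hi = max(s, s2), min(e, e2)
        if hi > lo:
            covered += (hi - lo).total_seconds()
    return covered / total


def _truth_for_scale(result: SimResult, scale: str, min_duration_h: float):
    states = SMALL_STATES if scale == "small" else LARGE_STATES
    ivs = truth_intervals(result, states)
    return [
        iv
        for iv in interval_union(ivs)
        if (iv[1] - iv[0]).total_seconds() / 3600.0 >= min_duration_h
    ]


@dataclass
class RecoveryCounts:
    n_truth: int = 0
    n_recovered: int = 0
    n_detected: int = 0
    n_true_positive: int = 0

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return (
            self.n_true_positive / self.n_detected if self.n_detected else float("nan")
        )

    def __iadd__(self, other: "RecoveryCounts") -> "RecoveryCounts":
        self.n_truth += other.n_truth
        self.n_recovered += other.n_recovered
        self.n_detected += other.n_detected
        self.n_true_positive += other.n_true_positive
        return self


def score_recovery(
    result: SimResult,
    patches: list[ARSPatch],
    scale: str,
    min_cover: float = 0.5,
) -> RecoveryCounts:
    """Interval-level recovery of planted search bouts at one scale group."""
    track = result.track
    margin = pd.Timedelta(hours=BORDER_MARGIN_H[scale])
    t0, t1 = track.times[0], track.times[-1]

    detected = interval_union(
        [(p.start, p.end) for p in patches if p.scale_class == scale]
    )
    truth_scorable = [
        iv
        for iv in _truth_for_scale(result, scale, MIN_TRUTH_H[scale])
        if iv[0] >= t0 + margin and iv[1] <= t1 - margin
    ]
    truth_any = _truth_for_scale(result, scale, 0.0)

    counts = RecoveryCounts()
    counts.n_truth = len(truth_scorable)
    counts.n_recovered = sum(
        overlap_fraction(iv, detected) >= min_cover for iv in truth_scorable
    )
    counts.n_detected = len(detected)
    counts.n_true_positive = sum(
        any(min(e, e2) > max(s, s2) for s2, e2 in truth_any) for s, e in detected
    )
    return counts


def attendance_coverage(
    result: SimResult,
    descriptors: pd.DataFrame,
    min_bout_h: float = 0.5,
    border_margin_h: float = 1.5,
) -> tuple[float, float]:
    """(covered, total) seconds of vessel-attendance bouts lying inside
    detected boat-associated ARS patches.

    Bouts shorter than ``min_bout_h`` or running into the trip's final
    border zone (where FPT is undefined) are not scored.
    """
    te = result.track.times[-1]
    bouts = [
        iv
        for iv in truth_intervals(result, ("boat_follow",))
        if (iv[1] - iv[0]).total_seconds() / 3600.0 >= min_bout_h
        and iv[1] <= te - pd.Timedelta(hours=border_margin_h)
    ]
    if descriptors is None or len(descriptors) == 0:
        assoc_ivs: list = []
    else:
        assoc = descriptors[descriptors["boat_associated"].astype(bool)]
        assoc_ivs = list(
            zip(pd.DatetimeIndex(assoc["start"]), pd.DatetimeIndex(assoc["end"]))
        )
    covered = total = 0.0
    for iv in bouts:
        dur = (iv[1] - iv[0]).total_seconds()
        total += dur
        covered += overlap_fraction(iv, assoc_ivs) * dur
    return covered, total


def radar_within_range(result: SimResult, range_km: float = 5.0) -> tuple[int, int]:
    """(n_within_range, n_positive): positive radar fixes vs the 5-km truth."""
    pos = result.track.radar_count > 0
    n_pos = int(np.sum(pos))
    n_ok = int(np.sum(result.truth.nearest_boat_km[pos] <= range_km + 1e-9))
    return n_ok, n_pos
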