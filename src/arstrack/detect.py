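"""Multi-scale ARS detection: FPT ladder, segmentation, classification, merge.

Small-scale radii (2-10 km) are analysed on daylight subtracks only, with
the day's mean FPT as classification threshold, because night-resting birds
drifting on the water would otherwise be flagged as fine-scale search.
Large and very-large radii run on the full trip (large ARS can span several
days) with the whole trip's mean FPT as threshold.  Within each scale group
the ARS time intervals found at the different radii are merged by interval
union into :class:`~arstrack.tracks.ARSPatch` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fpt import compute_fpt, longest_defined_run, pairwise_distances
from .lavielle import classify_segments, lavielle_segment
from .preprocess import daylight_mask, resample_equal_distance, split_daylight_subtracks
from .tracks import ARSPatch, DaylightMask, ResampledPath, Track

log = logging.getLogger(__name__)

SCALE_CLASSES = ("small", "large", "very_large")


@dataclass
class RadiusLadder:
    """The fixed ladder of FPT radii and their scale grouping.

    The default ladder is 2, 5, 10, 20, 30, 40, 60, 80, 100, 125, 150 km
    grouped as small = {2, 5, 10}, large = {20, 30, 40, 60, 80},
    very_large = {100, 125, 150}.  30 km sits in the large group (it is
    between the small and very-large bands); a custom grouping can be
    supplied.
    """

    radii_km: tuple[float, ...] = (2, 5, 10, 20, 30, 40, 60, 80, 100, 125, 150)
    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii_km)
        if list(radii) != sorted(set(radii)):
            raise ValueError("radii must be strictly increasing")
        self.radii_km = radii
        if not self.groups:
            self.groups = {}
            for r in radii:
                if r <= 10:
                    self.groups[r] = "small"
                elif r <= 80:
                    self.groups[r] = "large"
                else:
                    self.groups[r] = "very_large"
            if 30.0 in self.groups:
                log.info("radius 30 km assigned to the 'large' scale group")
        else:
            self.groups = {float(r): g for r, g in self.groups.items()}
        missing = [r for r in self.radii_km if r not in self.groups]
        if missing:
            raise ValueError(f"radii without a scale group: {missing}")
        bad = [g for g in self.groups.values() if g not in SCALE_CLASSES]
        if bad:
            raise ValueError(f"unknown scale classes: {sorted(set(bad))}")

    def radii_of(self, scale: str) -> list[float]:
        return [r for r in self.radii_km if self.groups[r] == scale]


def _ars_intervals_one_radius(
    path: ResampledPath,
    radius_km: float,
    lmin: int,
    kmax: int,
    s_threshold: float,
    scale_lmin_with_radius: bool = True,
    cv_min: float = 0.1,
    distances: np.ndarray | None = None,
) -> tuple[list[tuple[pd.Timestamp, pd.Timestamp]], float] | None:
    """ARS time intervals for one radius on one path, or None if too short.

    The classification threshold is the mean of the defined FPT values of
    this path (the trip mean for large scales; the day mean when the path
    is one daylight subtrack).  A segment shorter than the radius under
    investigation is not interpretable at that scale, so by default the
    minimum segment length grows with the radius.  A profile whose
    coefficient of variation falls below ``cv_min`` carries only the smooth
    speed-fluctuation noise of transit movement and is treated as
    homogeneous (no ARS at this radius).
    """
    if scale_lmin_with_radius:
        lmin = max(lmin, int(np.ceil(radius_km / path.step_km)))
    series = compute_fpt(path, radius_km, distances=distances)
    lo, hi = longest_defined_run(series.values)
    if lo < 0 or (hi - lo + 1) < 2 * lmin:
        return None
    x = series.values[lo : hi + 1]
    threshold = float(np.mean(x))
    if threshold <= 0 or float(np.std(x)) / threshold < cv_min:
        return [], threshold
    seg = lavielle_segment(series, lmin=lmin, kmax=kmax, threshold=s_threshold)
    flags = classify_segments(seg, threshold)
    times = path.times
    intervals = [
        (times[s], times[e]) for (s, e), is_ars in zip(seg.bounds, flags) if is_ars
    ]
    return intervals, threshold


def merge_scale_intervals(
    per_radius: dict[float, list[tuple]],
    thresholds: dict[float, float],
    track: Track,
    scale: str,
    merge_gap_h: float = 0.1,
    merge_radii: bool = False,
) -> list[ARSPatch]:
    """Build ARSPatch objects for one scale group.

    By default each radius contributes its own patches (one ARS segment at
    one radius = one patch), so patch counts and descriptors refer to a
    well-defined scale; contiguous ARS intervals within a radius are
    joined.  With ``merge_radii`` the intervals of all radii in the group
    are collapsed by interval union instead (useful for time-budget
    summaries).  Segment boundaries are quantised to resampled vertices,
    so gaps up to ``merge_gap_h`` are closed during either merge.
    """
    events = []
    for r, ivs in per_radius.items():
        for s, e in ivs:
            events.append((s, e, r))
    if not events:
        return []
    gap = pd.Timedelta(hours=merge_gap_h)
    groups = [events] if merge_radii else [
        [ev for ev in events if ev[2] == r] for r in sorted(per_radius)
    ]
    merged: list[list] = []
    for evs in groups:
        evs.sort(key=lambda ev: ev[0])
        block: list[list] = []
        for s, e, r in evs:
            if block and s <= block[-1][1] + gap:
                block[-1][1] = max(block[-1][1], e)
                block[-1][2].add(r)
            else:
                block.append([s, e, {r}])
        merged.extend(block)
    merged.sort(key=lambda b: b[0])
    times = track.times
    patches = []
    for s, e, radii in merged:
        radii = tuple(sorted(radii))
        members = np.flatnonzero((times >= s) & (times <= e))
        if len(members) < 2:
            continue
        patches.append(
            ARSPatch(
                bird_id=track.bird_id,
                scale_class=scale,
                start=s,
                end=e,
                radii_km=radii,
                thresholds_h=tuple(thresholds[r] for r in radii),
                fix_indices=members,
            )
        )
    return patches


def detect_ars_multiscale(
    track: Track,
    ladder: RadiusLadder | None = None,
    *,
    step_km: float = 1.0,
    lmin: int = 5,
    kmax: int = 30,
    s_threshold: float = 0.75,
    scale_lmin_with_radius: bool = True,
    merge_gap_h: float = 0.1,
    merge_radii: bool = False,
    twilight_deg: float = -6.0,
    mask: DaylightMask | None = None,
) -> list[ARSPatch]:
    """Detect ARS patches at every ladder radius and merge by scale group.

    ``track`` should already be speed-filtered.  Radii for which the trip
    (or a daylight subtrack) is too short are skipped with a log message.
    Deterministic: no random element anywhere in the chain.
    """
    ladder = ladder or RadiusLadder()
    if mask is None:
        mask = daylight_mask(track, threshold=twilight_deg)

    patches: list[ARSPatch] = []

    # --- large and very-large scales: full trip, trip-mean threshold
    try:
        full_path = resample_equal_distance(track, step_km)
    except ValueError as exc:
        log.warning("trip %s not resampleable: %s", track.bird_id, exc)
        return []
    full_D = pairwise_distances(full_path)
    for scale in ("large", "very_large"):
        per_radius: dict[float, list] = {}
        thresholds: dict[float, float] = {}
        for r in ladder.radii_of(scale):
            res = _ars_intervals_one_radius(
                full_path, r, lmin, kmax, s_threshold, scale_lmin_with_radius,
                distances=full_D,
            )
            if res is None:
                log.info("trip %s too short for radius %g km; skipped", track.bird_id, r)
                continue
            per_radius[r], thresholds[r] = res
        patches.extend(merge_scale_intervals(per_radius, thresholds, track, scale, merge_gap_h, merge_radii))

    # --- small scales: daylight subtracks, day-mean threshold
    per_radius = {r: [] for r in ladder.radii_of("small")}
    thresholds_small: dict[float, list] = {r: [] for r in per_radius}
    for sub in split_daylight_subtracks(track, mask):
        try:
            sub_path = resample_equal_distance(sub, step_km)
        except ValueError:
            continue
        sub_D = pairwise_distances(sub_path)
        for r in per_radius:
            res = _ars_intervals_one_radius(
                sub_path, r, lmin, kmax, s_threshold, scale_lmin_with_radius,
                distances=sub_D,
            )
            if res is None:
                continue
            ivs, thr = res
            per_radius[r].extend(ivs)
            thresholds_small[r].append(thr)
    mean_thr = {
        r: (float(np.mean(v)) if v else np.nan) for r, v in thresholds_small.items()
    }
    patches.extend(merge_scale_intervals(per_radius, mean_thr, track, "small", merge_gap_h, merge_radii))

    patches.sort(key=lambda p: (SCALE_CLASSES.index(p.scale_class), p.start))
    return patches


def compute_nesting(
    small: list[ARSPatch],
    large: list[ARSPatch],
    min_overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Nesting of small-scale patches inside large-scale patches.

    A small patch is *nested* when at least ``min_overlap`` of its duration
    (boundary inclusive) overlaps some large patch.  Returns
    ``(nested_flags, per_large_proportions)`` where the latter is, for each
    large patch, the fraction of the trip's small patches nested within that
    patch's own interval (0 when the trip has no small patches).
    """
    nested = np.zeros(len(small), dtype=bool)
    per_large = np.zeros(len(large))
    overlaps = np.zeros((len(small), len(large)))
    for i, sp in enumerate(small):
        dur = (sp.end - sp.start).total_seconds()
        if dur <= 0:
            continue
        for j, lp in enumerate(large):
            lo = max(sp.start, lp.start)
            hi = min(sp.end, lp.end)
            ov = max(0.0, (hi - lo).total_seconds())
            overlaps[i, j] = ov / dur
        nested[i] = overlaps[i].max(initial=0.0) >= min_overlap
    if small:
        for j in range(len(large)):
            per_large[j] = np.mean(overlaps[:, j] >= min_overlap)
    return nested, per_large
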