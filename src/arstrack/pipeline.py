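"""End-to-end orchestration: filter -> detect -> describe -> associate."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .bathymetry import DepthGrid
from .config import RunConfig
from .descriptors import TripSummary, describe_patches, find_encounters, summarize_trip
from .detect import detect_ars_multiscale
from .preprocess import daylight_mask, filter_speed
from .tracks import ARSPatch, Encounter, Track

log = logging.getLogger(__name__)


@dataclass
class TripResult:
    track: Track  # speed-filtered
    patches: list[ARSPatch]
    descriptors: pd.DataFrame
    encounters: list[Encounter]
    summary: TripSummary


def analyse_trip(
    track: Track, config: RunConfig | None = None, grid: DepthGrid | None = None
) -> TripResult:
    """Run the full per-trip analysis chain with the given constants."""
    config = config or RunConfig()
    filtered = filter_speed(track, vmax=config.vmax_kmh)
    mask = daylight_mask(filtered, threshold=config.twilight_deg)
    patches = detect_ars_multiscale(
        filtered,
        config.ladder(),
        step_km=config.step_km,
        lmin=config.lmin,
        kmax=config.kmax,
        s_threshold=config.s_threshold,
        mask=mask,
    )
    table = describe_patches(
        filtered,
        patches,
        mask,
        grid,
        on_water_kmh=config.on_water_kmh,
        depth_cutoff=config.depth_cutoff_m,
        nesting_min_overlap=config.nesting_min_overlap,
    )
    encounters = find_encounters(filtered, gap_hours=config.encounter_gap_h)
    summary = summarize_trip(
        filtered,
        patches,
        encounters,
        mask,
        nesting_min_overlap=config.nesting_min_overlap,
    )
    log.info(
        "trip %s: %d patches (%d small, %d large), %d encounters",
        track.bird_id,
        len(patches),
        sum(p.scale_class == "small" for p in patches),
        sum(p.scale_class == "large" for p in patches),
        len(encounters),
    )
    return TripResult(
        track=filtered,
        patches=patches,
        descriptors=table,
        encounters=encounters,
        summary=summary,
    )
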