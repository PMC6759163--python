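# arstrack

Multi-scale area-restricted-search (ARS) detection and fishing-vessel
association for seabird GPS tracks carrying a radar-detection channel.

Albatrosses are strongly attracted to fishing boats, and attending a boat
looks, in a GPS track, much like natural foraging: the bird slows down,
turns more, and stays in one area. Radar-detection loggers resolve the
ambiguity — they record a count whenever ship radar is heard within
~5 km (one scan per five minutes) — but turning raw tracks plus radar
counts into comparable behavioural units takes a pipeline:

1. **Quality control**: drop fixes implying > 100 km/h; resample each
   trip to one vertex per km of path; classify day/night by solar
   elevation against civil twilight (−6°).
2. **Multi-scale ARS detection**: first-passage time FPT(r) — the time to
   traverse a circle of radius r centred on each vertex, backward plus
   forward crossing — over the fixed radius ladder 2…150 km; each profile
   is segmented by the Lavielle penalized-contrast method (exact dynamic
   programming; the number of segments chosen by the second-difference
   rule at S = 0.75); a segment is ARS when its mean FPT exceeds the
   trip mean (large scales) or the day mean (small scales, daylight
   subtracks only).
3. **Descriptors**: per-patch duration, sinuosity
   (1 − straight/total distance), mean distance to colony, mean depth and
   shelf/oceanic habitat (−2200 m cutoff), duration-weighted time on
   water (< 10 km/h), night proportion, and nesting of small patches
   inside large ones.
4. **Association**: a patch is boat-associated iff any fix inside its
   interval has a positive radar count; encounters are maximal runs of
   detections separated by ≤ 2 h.
5. **Statistics**: a binomial GLMM (random intercept per bird, fitted by
   adaptive Gauss–Hermite maximum likelihood) contrasts natural and
   boat-associated patches, with marginal/conditional R² on the latent
   scale (logit residual variance π²/3).

Because radar-logger field datasets are rarely shareable, the package
includes a first-class simulator (`arstrack.simulate`) producing trips,
vessel tracks, duty-cycled radar detections and per-fix ground-truth
behavioural labels, so every stage is testable against known truth.
The intended users are movement ecologists who want a reproducible,
scriptable version of this analysis for their own logger data or for
method experiments on synthetic tracks.

## Worked example

Simulate two 14-h trips through a working fishery and run the whole
chain:

```bash
cat > fishery.yaml <<EOF
seed: 8
sim:
  trip_duration_h: 14
  n_boats: 12
EOF
arstrack all --config fishery.yaml --n-trips 2 --out demo
```

`demo/trip_summaries.csv` then contains (rounded):

```
bird_id  prop_time_small_ars  prop_time_large_ars  prop_time_with_boat  n_encounters  prop_radar_detections_in_ars  prop_small_nested
  bird8                0.530                0.821                0.291             2                         1.000              1.000
  bird9                0.534                0.555                0.357             3                         0.567              0.667
```

— bird8 spent 53% of the trip in small-scale ARS, had 2 radar encounters,
and every fix with a radar detection fell inside a detected ARS.
Aggregating `demo/descriptors.csv` by scale and association:

```
                              n   dur   sin
scale_class boat_associated
large       False             1  0.42  0.24
            True              8  5.23  0.69
small       False             2  1.93  0.45
            True             15  2.19  0.70
```

boat-associated small-scale patches are longer and more sinuous than the
natural ones — the qualitative contrast the radar logger was built to
expose. `demo/` also holds the raw tracks, encounters, a GeoJSON-ready
patch table (via `arstrack detect`), the fitted model (`model.csv`) and a
log echoing the full configuration and seed.

The same stages are available individually (`arstrack simulate | detect |
describe | associate | stats`) and as library functions
(`arstrack.analyse_trip` runs filter → detect → describe → associate on
one `Track`).

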