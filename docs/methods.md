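# Methods

`arstrack` re-implements, as a tested pipeline, the analysis used to ask
how albatrosses modify area-restricted search (ARS) when they encounter
fishing vessels: GPS tracks at 1-minute resolution carry a radar-detection
channel (the logger hears ship radar up to ~5 km, scanning one minute in
every five), ARS bouts are detected at multiple spatial scales from
first-passage-time (FPT) profiles segmented by the Lavielle
penalized-contrast method, each bout is described (duration, sinuosity,
depth/habitat, time on water, nesting), bouts containing at least one
radar detection are labelled boat-associated, and natural vs
boat-associated bouts are contrasted with a binomial random-intercept
GLMM. Because radar-logger field datasets are
rarely shareable, the package ships a first-class synthetic-data generator with per-fix
ground truth; every guarantee the test suite makes is a statement about
recovery of that known truth.

## Preprocessing

* **Speed filter.** Fixes implying ground speeds above 100 km/h are
  removed. The filter keeps the first fix and drops the *later* fix of
  any too-fast pair, recomputing speeds against the last retained fix
  until the condition holds; this single forward pass is idempotent. The
  choice of which fix to drop is a convention (standard biologging QC);
  the threshold is the study constant.
* **Equal-distance resampling.** Trips are re-discretised to one vertex
  per kilometre of along-path great-circle distance. Vertex 0 sits on the
  first fix; positions are spherical interpolations within the containing
  leg; the trailing partial segment is dropped. Times are interpolated
  linearly in distance within each leg (constant speed per leg). All
  distances use the haversine formula on a sphere of radius 6371 km;
  geodesic (ellipsoidal) corrections are ~0.3% and irrelevant at these
  scales.
* **Day/night.** Night is a solar elevation more than 6° below the
  horizon (civil twilight), computed with the NOAA low-accuracy solar
  equations (geometric elevation, no refraction; ~0.1° accuracy,
  equivalent to <1 min in twilight timing). Elevation is evaluated at
  each fix's own position and time — trips span tens of degrees of
  longitude, so the colony clock is not a valid proxy.

## Multi-scale ARS detection

FPT at radius *r* for a vertex is the time from the last backward
crossing of the circle of radius *r* centred on that vertex to the first
forward crossing, with crossing instants interpolated linearly along the
crossing leg. Vertices whose circle is never exited backward or forward
within the track are undefined (border effect, width ≈ *r*); the longest
defined run is analysed and border values are excluded from thresholds.

The radius ladder is fixed a priori: 2, 5, 10 (small), 20, 30, 40, 60,
80 (large), 100, 125, 150 km (very large). The 30 km radius is listed in
the ladder; we assign it to the large group (it sits between the small
and very-large bands) and log that assignment.

Each FPT profile is segmented by exact dynamic programming minimising the
within-segment sum of squared deviations, for every K up to Kmax = 30
with minimum segment length Lmin. K is chosen by the standard
penalized-contrast rule: rescale J(K) to decrease from Kmax to 1 and keep
the largest K whose second difference exceeds S = 0.75. Two guards make
the chain well-behaved on trivial input:

* **Radius-scaled Lmin.** A segment shorter than the radius under
  investigation is not interpretable at that scale, so Lmin(r) =
  max(5 vertices, r / step). This removes sub-scale slivers at large
  radii and skips radii the trip cannot resolve.
* **Homogeneity gate.** A profile whose coefficient of variation is below
  0.1 carries only the smooth speed-fluctuation noise of transit movement
  (a pure commute has CV ≈ 0.02–0.07 at every radius); it is treated as
  homogeneous and yields no ARS at that radius. Without the gate, the
  penalized contrast happily "finds" levels in autocorrelated noise and
  half of the resulting segments sit above the mean.

A segment is ARS when its mean FPT is strictly greater than the
reference: the whole trip's mean FPT at that radius for large and
very-large scales, and the day's mean for small scales. Small-scale
analysis runs on daylight subtracks only (a "day" is one maximal daylight
run between the night gaps); night fixes stay in the large-scale analysis
(large ARS can span nights) and the night share of each large patch is
carried as a descriptor instead.

**Patch construction.** Each ARS segment at each radius becomes one patch
(contiguous ARS intervals within a radius are joined; boundary
quantisation gaps up to 6 min are closed). An interval-union merge across
the radii of a scale group is available as an option and is what the
trip-level time-in-ARS proportions use, but per-radius patches are the
default unit of the descriptor table: the merged alternative produces
only 1–2 small patches per trip, an order of magnitude below per-trip
small-ARS counts reported for wandering-albatross tracking datasets, and
it lets the widest radius (10 km) dictate every small-scale boundary. Very-large-scale patches are
computed and reported but headline outputs use small + large only.

**Nesting.** A small patch is nested when ≥ 50% of its duration
(boundary-inclusive) overlaps a large patch; each large patch carries the
fraction of the trip's small patches nested within its own interval. The
50% rule is our definition — any-overlap and strict containment differ
only for boundary-straddling patches.

## Descriptors, association, encounters

* **Sinuosity** = 1 − (straight first-to-last distance) / (total path
  distance) within the patch: 0 for a straight path, 1 for a closed
  loop; a stationary patch is defined as 0.
* **Time on water**: duration-weighted fraction of inter-fix intervals
  slower than 10 km/h.
* **Depth and habitat**: bilinear interpolation of a bathymetry grid at
  each member fix (nearest-neighbour available); mean depth strictly
  below −2200 m is oceanic, otherwise shelf (a mean of exactly −2200 m is
  shelf).
* **Boat association**: a patch is boat-associated iff any original fix
  inside its (boundary-inclusive) time interval has a positive radar
  count. Radar counts live on original fixes only — they are never
  carried onto resampled vertices, which would double-count under
  resampling.
* **Encounters**: maximal runs of positive-radar fixes in which
  successive detections are at most 2 h apart; a strictly longer gap
  starts a new encounter.

## The mixed model

Natural vs boat-associated patches are contrasted with a logistic
regression carrying a Gaussian random intercept per bird:
logit P(associated) = x'β + b_bird, b ~ N(0, σ²). The likelihood is
maximised with the per-group integrals evaluated by adaptive
Gauss–Hermite quadrature (15 nodes re-centred on each group's posterior
mode), which reproduces `lme4::glmer` coefficients to ~2 decimals on
simulated data (cross-checked in the test suite via Rscript). Standard
errors come from the numerical observed information (central
differences); log σ is bounded below at −6 so the σ → 0 boundary of null
data terminates instead of drifting. Degenerate responses and
(quasi-)complete separation raise an explicit error rather than returning
the astronomically large z-values such fits would otherwise print.
Predictors enter on raw scales by default (standardization is a flag).

Marginal and conditional R² use the latent-scale decomposition with the
logit distribution-specific variance π²/3: R²m = σ²_f / (σ²_f + σ²_b +
π²/3), R²c = (σ²_f + σ²_b) / (same), with σ²_f the sample variance of the
fixed-effect linear predictor.

## The synthetic-data generator

One simulated trip is a state-switching movement model over five states —
commute, large_search, intensive_search, boat_follow, night_rest — at
1-minute steps. Headings wobble by von Mises turning angles with
per-state concentration; speeds are truncated normal per state (ceiling
95 km/h, so the 100 km/h filter removes nothing unless outliers are
explicitly injected via a flag). The defaults aim at the study system:
commutes near 65 km/h, searching flight 45 km/h, fine-scale search
13 km/h, vessel attendance ~10 km/h, night drift 3 km/h.

Search is *confined, not merely tortuous*: each search bout anchors a
patch centre, and the heading relaxes towards it with a pull growing
quadratically in relative displacement, so the bird sweeps arcs inside a
region instead of bouncing off a boundary. Large-scale patches have a
40 km radius and drift at 5 km/h along a per-trip "front" bearing;
intensive patches have a 2 km radius and drift at 10 km/h along the same
front (natural fine-scale search tracks moving prey structures and
therefore progresses; vessel attendance, by contrast, is a true loiter).
Intensive search is reachable only from large-scale search, which builds
the nested structure by construction; a worked patch is left depleted
(60 min refractory before re-entry, bouts capped at 4 h — memoryless
dwell times otherwise produce freak half-day bouts). Commuting birds
hold a per-bout goal bearing (goal-directed flight); a heading random
walk would slowly curl the commute into a false large-scale patch.

Vessels alternate straight cruising legs (~18 km/h, mean 1.5 h) with
fishing bouts (~2.5 km/h, mean 8 h) worked on a ground they do not leave
by more than 2 km. Birds notice an operating vessel within 30 km
(attraction range), steer towards it, and may lock into following once
inside the 5-km radar range (p = 0.3/min); they leave a working vessel
slowly (p = 0.0025/min), abandon one that steams off almost immediately,
keep searching the local offal trail after leaving, and ignore vessels
for 90 min afterwards. Radar counts are emitted only at the 5-minute
duty-cycle instants when a vessel is within 5 km. Night (sun < −6°)
forces resting on the water. The single seed fans out through
`SeedSequence.spawn` into per-entity substreams, so adding a vessel never
perturbs the bird's draw sequence.

Vessel placement is area-uniform in a 40–250 km annulus around the
colony, matching the radial band where the simulated birds search. Vessels in
this system are observable only through the radar channel, so all fleet
kinematics are generator choices, not claims about real fisheries.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: 1-min
fixes with a duty-cycled 5-km radar channel, flight speeds up to
~100 km/h, night resting, nested multi-scale search patches, vessel
attendance, and time budgets typical of wandering-albatross tracking
studies (~20% of time in fine-scale search, ~40–50% in large-scale
search, boat-associated
fine-scale bouts longer and more sinuous than natural ones). It does not
model wind-dependent flight, olfactory search, prey fields, fleet
economics, or sex/age effects; passing tests therefore demonstrate that
the *pipeline* recovers known behavioural structure under realistic
sampling, not that real albatrosses behave like the generator.

## Evaluation conventions

Detection is scored at interval level against the generator's state
labels. A truth bout is recovered when ≥ 50% of its duration is covered
by detected patches of the matching scale; sensitivity is computed over
bouts the method can physically see (clear of the track ends by a border
margin — 1.5 h at large scales, 15 min at small — and at least as long
as the scale can resolve: 0.5 h small, 2 h large). A detected patch is a
true positive when it overlaps *any* true search interval of its scale
(no duration floor): FPT genuinely smears every detection outward by
about one radius of path, and firing on a short real bout is not a false
alarm. Attendance fidelity is the duration-weighted fraction of
boat-following bouts covered by boat-associated patches, excluding bouts
that run into the trip's final border zone.

## Problem sizes and numerical choices

The shipped studies use 10–14 h single-daylight trips for detection
scoring (50 trips), 38 h two-day trips for attendance fidelity, replicate
batches of 10 fleet-dense trips for the descriptor contrast (50
replicates), and n = 2000 × 20 birds for mixed-model calibration (50 + 50
replicates); these sizes give stable rates while keeping the full suite
in single-digit minutes on one core. Further conventions: ties at the
classification threshold are not ARS; single-row strata report sd 0;
longitudes live in [−180, 180]; all timestamps are UTC; the FPT distance
matrix is computed once per path and shared across the radius ladder.

## Known limitations

* ARS at a trip's start and end is undetectable in principle (no backward
  or forward crossing) — the border effect grows with the radius.
* A trip spent almost entirely in one behaviour (e.g. a whole day behind
  one vessel) has a flat FPT profile; mean-threshold classification then
  finds little or nothing. Multi-day trips dilute the problem, which is
  why the attendance-fidelity study uses two-day trips.
* The day-mean small-scale threshold couples patches within a day: one
  very long attendance raises the threshold and can mask weak natural
  bouts the same day.
* The mixed model covers a single random intercept (the bird); no random
  slopes, no crossed effects, and z-based inference only.
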