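# Methods

## Geometry

All computation is on a sphere of radius R = 6371.0088 km (IUGG mean
radius). Distances are haversine great circles; intermediate points use
spherical linear interpolation. Source GIS workflows for this kind of
analysis are typically planar or of unstated datum; a sphere is symmetric,
reproducible, and accurate to ~0.3% of the ellipsoid at these scales —
far below the km-level reporting precision of the derived statistics.

Latitude-crossing longitudes are interpolated **linearly in lon–lat
(plate-carrée) space**, not along the geodesic. Two reasons: observed
route segments are at most a few degrees long, where the two differ
negligibly; and the segment-permutation null operates on lon–lat
displacement vectors, so using the same planar interpolation keeps the
observed route and its randomizations exactly comparable. The "linear
distance" between two crossings on the same parallel is the great-circle
distance between the two same-latitude points (not the along-parallel
arc); the difference is <0.1% at the study latitudes.

Longitudes live in [−180, 180) and no segment may span ≥180° of
longitude; the study area (70–110°E) never approaches the antimeridian,
so violations raise an error rather than being wrapped silently.

## Plausibility filter

Doppler telemetry mixes accuracy-assigned location classes (1–3, error
radii 150–1,000 m) with unassigned classes (0, A, B, Z). The filter is a
simplified distance–rate–angle screen: a fix is dropped when (a) the speed
implied from the previously retained fix exceeds `max_speed`, or (b) it is
a spike — internal turning angle below `min_spike_angle` with both
adjacent steps above `max_step`. Classes 1–3 and the first/last fixes are
exempt. Defaults (`max_speed` 100 km/h, `min_spike_angle` 15°, `max_step`
100 km) pass plausible gull flight and reject Doppler spikes; all three
are configurable, and the pass is iterated to a fixed point so the filter
is idempotent. This is deliberately not a re-implementation of any
specific hybrid filter product; it captures the three stated criteria in
an auditable form.

## Journey timing

Departure/arrival detection needs an explicit rule to be reproducible.
A bird has departed once it permanently leaves a `site_radius_km` disc
(default 25 km) around the origin site, and has arrived at the first fix
of its final uninterrupted stay inside the destination disc. When a
transmission gap spans a transition (duty-cycled transmitters guarantee
some), the assigned date is the median of the flanking fix dates —
midpoint rounded **down** to the earlier whole day (the rounding direction
is a free choice; down is fixed here and applied consistently). Duration
is the whole-day difference arrival − departure, floored at 1. Journeys
that never leave the origin or never settle at the destination raise an
"incomplete journey" error; the pipeline logs and skips them, since real
telemetry datasets routinely contain such tracks.

Trans-plateau duration uses first entry to last exit of the plateau
polygon (a route with multiple plateau visits yields one figure; the
per-route single number cannot disambiguate more). Trans-plateau distance
clips the route polyline against the polygon with linear boundary-crossing
interpolation and sums great-circle lengths of the inside pieces. Mean
altitude is the mean of an optional plain-text elevation raster sampled
nearest-cell at route vertices; no raster ships with the package.

## Route-randomization null

A randomized route keeps the observed multiset of lon–lat displacement
vectors and shuffles their order uniformly. Because vector addition
commutes, every permutation reproduces the observed start **and** end
points exactly — the property that anchors the comparison. (Independent
re-orientation of segments would not preserve the endpoint; permutation is
the construction consistent with fixed endpoints.) Defaults: 1,000
randomizations, test parallels every 3° from 23°N to 44°N.

At a parallel, a route that doubles back may cross several times; the
crossing farthest from the reference longitude is used ("most-deviated
crossing"), with ties broken toward travel order. The reference is the
discretized geodesic's crossing at that parallel — the deviation concept
throughout is relative to the expected shortest route. Randomized routes
that never reach the parallel contribute nothing and are counted in
metadata. The observed crossing's percentile uses the mid-rank convention
(ties split evenly), and significance is two-tailed: below 100·α/2 or
above 100·(1 − α/2), α = 0.05.

The full batch of permutations is drawn as one vectorized operation from
a seeded generator, so a fixed seed gives a bit-reproducible null
distribution and the 2,000-replicate calibration check runs in seconds.
Type-I error calibrates to ~5% (measured 4.9–5.5% across seeds).

## Detour extent

The expected shortest route is the geodesic discretized at 201 vertices
(path length within 0.005% of the direct great-circle distance; a geodesic
crosses each parallel between these terminals exactly once). Longitudinal
detour at a parallel is the same-latitude great-circle separation between
observed and expected crossings. Latitudinal overshoot is the maximum
meridian distance of any vertex beyond the terminal's latitude in the
stated direction — measured along the meridian at the vertex's longitude,
a fixed convention noted in output metadata. Additional detour distance is
cumulative − shortest, also as a percentage of shortest; cumulative below
shortest is an upstream-bug signal and raises.

## Habitat corridors

"Proximity to water" is the percent of a corridor's area covered by water
polygons — the only operationalization consistent with unit-less
percentages. The corridor is the polyline buffered by 100 km (default) in
a local azimuthal-equidistant projection centred on the route midpoint.
On the sphere this projection is exact in distance/azimuth from the
centre with area distortion ≈ c²/6 for angular distance c: under 0.5% at
1,500 km from centre, well below reporting precision (the stadium-area
closed form is matched to 0.005% on a 1,000-km test route). Observed and
expected corridors for one journey share one projection, so the paired
difference is internally consistent. An optional clipping polygon can
restrict the analysis to a sub-region before buffering.

## Repeatability and trend

With individuals as groups, one-way ANOVA mean squares give
s²_W = MS_within and s²_A = (MS_among − MS_within)/n₀ with
n₀ = (N − Σnᵢ²/N)/(a − 1), and r = s²_A/(s²_A + s²_W) — the classical
moment estimator for the intraclass correlation with unequal group sizes.
A REML mixed model would differ only in edge cases at these sample sizes;
the moment estimator is transparent and admits the occasional negative r
(MS_among < MS_within), which is reported as-is rather than truncated, so
flexible variables can show r slightly below zero. F = MS_among/MS_within
with (a − 1, N − a) degrees of freedom gives the p-value.

The trend in the fraction of significantly deviating routes across
parallels uses the Cochran–Armitage score test with equally spaced scores
(the parallels are equally spaced at 3°), df = 1. Only the binary
deviation indicator is tested; a trend test on the continuous extents is
not implemented.

## Synthetic generator

The generator emulates the study regime: 4 individuals tracked 2–4 years
(default journey counts 4, 3, 2, 3), both seasons, between 100.2°E/36.8°N
and 90°E/22°N, with an 8 h on / 15 h off duty cycle and ~3 fixes per
on-window. The detour is a raised-cosine longitudinal bump
Δlon(φ) = A·w(φ)/(111.195·cos φ) with w a cosine window (default peak
35°N, half-width 9°), so the per-parallel deviation has the analytically
known maximum A at the peak. Individual amplitude offsets are Gaussian
(default between-individual SD 200 km) drawn once per individual and
reused across years; within-individual noise (default SD 100 km) is drawn
per journey, giving an expected route repeatability of
200²/(200² + 100²) = 0.8, in the range reported for real route variables.
Season means default to 450 km (autumn) and 300 km (spring) — autumn
detours larger, matching the loop-migration asymmetry. Amplitudes truncate
at 0. Departure days: day-of-year 221 (autumn) / 74 (spring), between-SD
6 d, within-SD 4 d. Position error is zero-mean Gaussian by location class
(0.15 km for LC 3 up to 20 km for Z) with a class mix giving roughly a
third high-quality fixes.

The world layers are consistent by construction: a rectangular plateau
polygon straddling the mid-latitudes, an elevation raster that is 4,500 m
inside it and 1,500 m outside, and a water layer of disjoint equal-area
squares summing exactly to the configured total (default 6,000 km²),
70% placed along the detour corridor east of the geodesic and the rest
just west of it — so observed corridors are wetter than shortest-route
corridors by design, and the paired comparison has a known positive sign.

What the generator does **not** emulate: stopover residence dynamics,
wind and weather covariates, altitude-dependent behaviour, and the heavy
non-Gaussian tails of real Argos error. Passing tests therefore establish
that the estimators recover known structure under idealized error, not
that any particular field dataset meets those assumptions.

## Problem sizes and determinism

Test and validation runs use deliberately small but sufficient sizes: the
null-model calibration uses a 50-segment route, 500 randomizations and
2,000 replicates; amplitude recovery uses 50 noisy journeys; repeatability
recovery uses 30 individuals × 5 years × 200 replicates. All randomness
flows from numpy `default_rng` seeds; a pipeline rerun with the same
configuration and seed is byte-identical, and every output CSV header
records the package version, a configuration hash and the seed.

## Known limitations

* Spherical earth; no ellipsoidal geodesics or rhumb lines.
* The crossing interpolation and the null model are planar in lon–lat by
  design; both are tied to segment lengths of at most a few degrees.
* Arrival detection requires the final fix run to sit inside the site
  radius; very noisy terminal fixes can render a genuine journey
  "incomplete" (logged and skipped rather than guessed).
* The repeatability estimator assumes a single grouping factor; season
  must be analysed separately, and no individual × season interaction is
  estimated.
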