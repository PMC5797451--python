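# migdetour

Detour analysis for satellite-tracked bird migrations.

Long-distance migrants confronted with a high-altitude barrier — the
motivating system is Pallas's Gull crossing the Qinghai-Tibetan Plateau
between a breeding lake near 100.2°E, 36.8°N and a wintering coast near
90°E, 22°N — often trade distance for hospitable ground, producing
longitudinal detours away from the great-circle route. This package turns
Doppler (Argos-style) tracking fixes into the standard detour statistics of
that literature, for movement ecologists who want the whole chain in one
tested, scriptable pipeline:

* **Journey metrics** — departure/arrival dates under an explicit radius
  rule with a median-date rule for transmission gaps; shortest (great-circle)
  distance *D*, cumulative route distance *L*, speed *L*/duration,
  straightness index *S = D/L ∈ (0, 1]*, and trans-plateau
  distance/duration/speed for the route portion inside a ≥3,000 m region
  polygon.
* **Route-randomization null model** — each observed route is compared with
  *n* = 1,000 randomized routes built by uniformly permuting its lon–lat
  displacement vectors (start and end points preserved exactly). The
  crossing longitude at each 3° parallel from 23°N to 44°N is deemed a
  significant detour when it falls below the 2.5th or above the 97.5th
  percentile of the randomized crossings (two-tailed, *P* = 0.05, mid-rank
  percentiles).
* **Detour extent** — per-parallel great-circle separation between the
  observed route's most-deviated crossing and the geodesic's crossing;
  latitudinal overshoot past a terminal site; additional detour distance
  *L − D* and its percentage.
* **Habitat association** — percent water cover inside 100-km buffer
  corridors around the observed versus the expected shortest route, compared
  pairwise per journey.
* **Repeatability** — intraclass correlation *r* = σ²_B/(σ²_B + σ²_W) from
  one-way ANOVA variance components with effective group size
  *n₀ = (N − Σnᵢ²/N)/(a − 1)*, plus a Cochran–Armitage trend test on the
  fraction of significantly deviating routes across parallels.
* **Synthetic data** — a generator with known ground truth (per-individual
  detour amplitudes, Argos-like error by location class, 8 h on / 15 h off
  duty cycles) and matching plateau/water/elevation layers, so every stage
  is testable offline.

## Worked example

```
migdetour run-all --seed 7 --out-dir demo --n-random 500
```

simulates 4 individuals × 2–4 years × both seasons and writes six CSV
tables. One simulated journey that never re-enters the 25-km destination
radius (a noisy terminal fix) is logged and skipped — per-journey error
isolation, not a failure. Typical output, from `summaries.csv`:

```
G1,autumn,2006,2006-08-08,2006-10-10,63,1916.6,3556.4,56.5,0.539,2743.5,...
```

i.e. a 63-day autumn journey whose route of 3,556 km covers a 1,917-km
great-circle gap (straightness 0.54), 2,744 km of it across the plateau.
`deviation_bins.csv` shows the detour signature the null model detects —
mean longitudinal deviation growing toward the northern parallels, with the
significant fraction rising the same way (autumn, seed 7):

```
latitude  mean_deviation_km  significant_fraction
    23.0                3.5                  0.00
    29.0              100.9                  0.00
    32.0              303.6                  0.92
    35.0              397.3                  1.00
```

`repeatability.csv` recovers the generator's design: route variables such
as the longitude crossing 35°N are highly repeatable (*r* = 0.82,
*P* = 0.001 at seed 7) because individual detour amplitudes persist across
years, while timing variables are noisier. `habitat.csv` shows the observed
corridors wetter than the shortest-route corridors (+0.37 percentage points
paired mean difference), as constructed in the synthetic world.

The same stages are importable as a library (`migdetour.deviation_profile`,
`migdetour.anova_components`, ...); see `docs/methods.md` for the science
and the numerical choices.

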