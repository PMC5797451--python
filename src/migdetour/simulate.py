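"""Synthetic tracking data with known ground truth.

The generator emulates a small satellite-tracked population migrating
between a breeding site on a high plateau (default near 100.2E, 36.8N)
and a coastal wintering site (default near 90E, 22N): a handful of
individuals, each followed for several years and both seasons, with

* individual-specific detour amplitudes (a per-individual random effect,
  constant across years) plus year-to-year noise — this is what makes
  repeatability recoverable downstream;
* a smooth raised-cosine longitudinal bump as the detour shape, so the
  maximum deviation at the peak parallel equals the drawn amplitude
  analytically;
* an optional poleward overshoot leg past the breeding site;
* Doppler-like position error by location class and duty-cycle gaps
  (default 8 h on / 15 h off) in the fix schedule.

``make_world`` builds a matching plateau polygon, elevation raster and
water layer (with water optionally concentrated along the detour corridor)
of known total area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from .argos import Fix, LOC_CLASSES
from .geodesy import GeoPoint, KM_PER_DEGREE, Polyline, gc_intermediate
from .journeys import ElevationRaster, Journey, RegionPolygon
from .habitat import WaterLayer

#: Argos-like 1-sigma position error by location class, km.
DEFAULT_ERROR_SD_KM = {
    "3": 0.15, "2": 0.35, "1": 1.0, "0": 3.0, "A": 5.0, "B": 10.0, "Z": 20.0,
}
#: Class mix giving roughly a third high-quality (LC 1-3) fixes.
DEFAULT_CLASS_PROBS = {
    "3": 0.07, "2": 0.10, "1": 0.16, "0": 0.15, "A": 0.20, "B": 0.30, "Z": 0.02,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 4
    years_per_individual: tuple[int, ...] = (4, 3, 2, 3)
    first_year: int = 2006
    seasons: tuple[str, ...] = ("autumn", "spring")
    origin: GeoPoint = field(default_factory=lambda: GeoPoint(100.2, 36.8))
    destination: GeoPoint = field(default_factory=lambda: GeoPoint(90.0, 22.0))
    # Detour geometry: raised-cosine bump in longitude, peak at peak_lat
    detour_amplitude_mean_km: dict = field(
        default_factory=lambda: {"autumn": 450.0, "spring": 300.0}
    )
    between_individual_sd_km: float = 200.0
    within_individual_sd_km: float = 100.0
    detour_peak_lat: float = 35.0
    detour_halfwidth_deg: float = 9.0
    overshoot_km: float = 0.0  # poleward leg past the breeding site (autumn)
    # Timing: departure day-of-year per season, duration of travel
    departure_doy_mean: dict = field(default_factory=lambda: {"autumn": 221, "spring": 74})
    departure_between_sd_days: float = 6.0
    departure_within_sd_days: float = 4.0
    duration_mean_days: dict = field(default_factory=lambda: {"autumn": 60.0, "spring": 35.0})
    duration_sd_days: float = 8.0
    # Sampling regime
    duty_on_h: float = 8.0
    duty_off_h: float = 15.0
    fixes_per_on_window: int = 3
    stay_days: float = 3.0  # residence at each terminal site before/after travel
    error_sd_km: dict = field(default_factory=lambda: dict(DEFAULT_ERROR_SD_KM))
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    n_route_vertices: int = 201
    # World geometry
    plateau_bounds: tuple[float, float, float, float] = (84.0, 26.0, 104.0, 38.0)
    water_total_area_km2: float = 6000.0
    water_on_detour_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if len(self.years_per_individual) != self.n_individuals:
            if len(self.years_per_individual) == 1:
                object.__setattr__(
                    self, "years_per_individual",
                    self.years_per_individual * self.n_individuals,
                )
            else:
                raise ValueError("years_per_individual length must match n_individuals")
        for sd in (self.between_individual_sd_km, self.within_individual_sd_km,
                   self.departure_between_sd_days, self.departure_within_sd_days,
                   self.duration_sd_days):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.fixes_per_on_window < 1:
            raise ValueError("fixes_per_on_window must be >= 1")


@dataclass(frozen=True)
class IndividualEffects:
    """Per-individual random effects, drawn once and reused across years."""

    animal_id: str
    amplitude_offset_km: float
    departure_offset_days: float
    detour_sign: float  # +1 east of the geodesic, -1 west


@dataclass(frozen=True)
class SimulatedJourney:
    journey: Journey
    true_route: Polyline
    true_amplitude_km: float
    true_departure_doy: float


def _raised_cosine(lat: np.ndarray, peak: float, halfwidth: float) -> np.ndarray:
    w = np.zeros_like(lat)
    inside = np.abs(lat - peak) < halfwidth
    w[inside] = 0.5 * (1.0 + np.cos(np.pi * (lat[inside] - peak) / halfwidth))
    return w


def true_detour_route(
    origin: GeoPoint,
    destination: GeoPoint,
    amplitude_km: float,
    peak_lat: float,
    halfwidth_deg: float,
    n_vertices: int = 201,
    overshoot_km: float = 0.0,
) -> Polyline:
    """Geodesic warped by a raised-cosine longitudinal bump.

    The eastward shift at latitude L is
    ``amplitude_km * w(L) / (KM_PER_DEGREE * cos L)`` degrees with w the
    raised-cosine window, so the deviation from the geodesic measured
    along parallels peaks at ``amplitude_km`` at ``peak_lat`` (negative
    amplitudes bow the route west).  An optional poleward overshoot leg is
    prepended at the poleward terminal.
    """
    fr = np.linspace(0.0, 1.0, n_vertices)
    base = np.array(
        [gc_intermediate(origin, destination, f).as_tuple() for f in fr], dtype=float
    )
    base[0] = origin.as_tuple()
    base[-1] = destination.as_tuple()
    lats = base[:, 1]
    dlon = amplitude_km * _raised_cosine(lats, peak_lat, halfwidth_deg) / (
        KM_PER_DEGREE * np.cos(np.radians(lats))
    )
    warped = base.copy()
    warped[:, 0] += dlon
    warped[0] = origin.as_tuple()
    warped[-1] = destination.as_tuple()

    if overshoot_km > 0.0:
        poleward_first = abs(origin.lat) >= abs(destination.lat)
        term = origin if poleward_first else destination
        dlat = overshoot_km / KM_PER_DEGREE
        leg_out = [
            (term.lon, term.lat + dlat * f) for f in np.linspace(0.2, 1.0, 5)
        ]
        leg_back = [(term.lon, term.lat + dlat * f) for f in np.linspace(0.8, 0.2, 4)]
        leg = np.array(leg_out + leg_back, dtype=float)
        warped = (
            np.vstack([warped[:1], leg, warped]) if poleward_first
            else np.vstack([warped, leg[::-1], warped[-1:]])
        )

    dedup = [tuple(warped[0])]
    for row in warped[1:]:
        if tuple(row) != dedup[-1]:
            dedup.append(tuple(row))
    return Polyline(dedup)


def _fix_times(start: datetime, total_days: float, cfg: SimulationConfig,
               rng: np.random.Generator) -> list[datetime]:
    """Duty-cycle-gated fix times: bursts inside on-windows, gaps between."""
    cycle_h = cfg.duty_on_h + cfg.duty_off_h
    times = []
    t = 0.0
    while t < total_days * 24.0:
        offsets = np.sort(rng.uniform(0.0, cfg.duty_on_h, size=cfg.fixes_per_on_window))
        for off in offsets:
            if t + off < total_days * 24.0:
                times.append(start + timedelta(hours=float(t + off)))
        t += cycle_h
    return times


def _interp_along(route: Polyline, fractions: np.ndarray) -> np.ndarray:
    """Positions at given length-fractions along a polyline (lon-lat linear)."""
    from .geodesy import _gc_distance_arrays

    c = route.coords
    seg = _gc_distance_arrays(c[:-1, 0], c[:-1, 1], c[1:, 0], c[1:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    target = np.clip(fractions, 0.0, 1.0) * total
    idx = np.searchsorted(cum, target, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    seg_len = np.where(seg[idx] == 0.0, 1.0, seg[idx])
    t = (target - cum[idx]) / seg_len
    return c[idx] + t[:, None] * (c[idx + 1] - c[idx])


def simulate_journey(
    effects: IndividualEffects,
    season: str,
    year: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedJourney:
    """One journey: true warped route plus duty-cycled noisy fixes.

    Autumn runs breeding -> wintering, spring the reverse.  The journey
    includes short residence periods at both terminal sites so that
    departure/arrival detection has flanking fixes.
    """
    amp = effects.detour_sign * max(
        0.0,
        cfg.detour_amplitude_mean_km[season]
        + effects.amplitude_offset_km
        + rng.normal(0.0, cfg.within_individual_sd_km),
    )
    if season == "autumn":
        o, d = cfg.origin, cfg.destination
        overshoot = cfg.overshoot_km
    else:
        o, d = cfg.destination, cfg.origin
        overshoot = cfg.overshoot_km

    route = true_detour_route(
        o, d, amp, cfg.detour_peak_lat, cfg.detour_halfwidth_deg,
        n_vertices=cfg.n_route_vertices,
        overshoot_km=overshoot if season == "autumn" else 0.0,
    )

    doy = (
        cfg.departure_doy_mean[season]
        + effects.departure_offset_days
        + rng.normal(0.0, cfg.departure_within_sd_days)
    )
    duration = max(5.0, cfg.duration_mean_days[season] + rng.normal(0.0, cfg.duration_sd_days))
    dep_time = datetime(year, 1, 1, tzinfo=timezone.utc) + timedelta(days=float(doy) - 1)
    start = dep_time - timedelta(days=cfg.stay_days)
    total_days = cfg.stay_days + duration + cfg.stay_days

    times = _fix_times(start, total_days, cfg, rng)
    travel_frac = np.array(
        [
            ((t - dep_time).total_seconds() / 86400.0) / duration
            for t in times
        ]
    )
    pos = _interp_along(route, np.clip(travel_frac, 0.0, 1.0))

    classes = rng.choice(
        list(cfg.class_probs), size=len(times), p=np.array(list(cfg.class_probs.values()))
    )
    fixes = []
    for (lon, lat), t, lc in zip(pos, times, classes):
        sd = cfg.error_sd_km[str(lc)]
        lat_n = lat + rng.normal(0.0, sd) / KM_PER_DEGREE
        lon_n = lon + rng.normal(0.0, sd) / (KM_PER_DEGREE * math.cos(math.radians(lat)))
        fixes.append(
            Fix(
                animal_id=effects.animal_id,
                timestamp=t,
                point=GeoPoint(float(lon_n), float(np.clip(lat_n, -90.0, 90.0))),
                loc_class=str(lc),
            )
        )
    journey = Journey(
        animal_id=effects.animal_id, season=season, year=year,
        fixes=tuple(fixes), origin=o, destination=d,
    )
    return SimulatedJourney(
        journey=journey, true_route=route,
        true_amplitude_km=float(abs(amp)), true_departure_doy=float(doy),
    )


def draw_individual_effects(cfg: SimulationConfig, rng: np.random.Generator
                            ) -> list[IndividualEffects]:
    out = []
    for i in range(cfg.n_individuals):
        out.append(
            IndividualEffects(
                animal_id=f"G{i + 1}",
                amplitude_offset_km=float(rng.normal(0.0, cfg.between_individual_sd_km)),
                departure_offset_days=float(rng.normal(0.0, cfg.departure_between_sd_days)),
                detour_sign=1.0,
            )
        )
    return out


def simulate_population(cfg: SimulationConfig
                        ) -> tuple[list[SimulatedJourney], pd.DataFrame]:
    """All journeys for the configured population, plus a ground-truth table.

    Individual random effects are drawn once and reused across years, so
    between- and within-individual variance downstream match the
    configured components.
    """
    rng = np.random.default_rng(cfg.seed)
    effects = draw_individual_effects(cfg, rng)
    journeys: list[SimulatedJourney] = []
    truth_rows = []
    for eff, n_years in zip(effects, cfg.years_per_individual):
        for k in range(n_years):
            year = cfg.first_year + k
            for season in cfg.seasons:
                # spring journey of year y happens in calendar year y+1
                cal_year = year + 1 if season == "spring" else year
                sj = simulate_journey(eff, season, cal_year, cfg, rng)
                journeys.append(sj)
                truth_rows.append(
                    {
                        "animal_id": eff.animal_id,
                        "season": season,
                        "year": cal_year,
                        "true_amplitude_km": sj.true_amplitude_km,
                        "true_departure_doy": sj.true_departure_doy,
                        "amplitude_offset_km": eff.amplitude_offset_km,
                        "departure_offset_days": eff.departure_offset_days,
                    }
                )
    return journeys, pd.DataFrame(truth_rows)


def make_world(cfg: SimulationConfig
               ) -> tuple[RegionPolygon, WaterLayer, ElevationRaster]:
    """Plateau polygon, water layer and elevation raster for the study box.

    The plateau is a rectangle straddling the route's mid-latitudes; the
    raster is 4,500 m inside it and 1,500 m outside, so every cell inside
    the polygon clears a 3,000 m threshold.  Water squares of known total
    area are split between a detour corridor (east of the geodesic around
    the bump peak) and scattered background positions.
    """
    rng = np.random.default_rng(cfg.seed + 10_000)
    x0, y0, x1, y1 = cfg.plateau_bounds
    plateau = RegionPolygon(box(x0, y0, x1, y1), label="plateau >= 3,000 m")

    # Elevation raster over a box generously covering the routes
    cell = 0.5
    lon_min, lon_max = 78.0, 112.0
    lat_min, lat_max = 14.0, 46.0
    ncols = int(round((lon_max - lon_min) / cell))
    nrows = int(round((lat_max - lat_min) / cell))
    lon_centers = lon_min + cell * (np.arange(ncols) + 0.5)
    lat_centers = lat_max - cell * (np.arange(nrows) + 0.5)  # north to south
    lon_g, lat_g = np.meshgrid(lon_centers, lat_centers)
    inside = (lon_g >= x0) & (lon_g <= x1) & (lat_g >= y0) & (lat_g <= y1)
    values = np.where(inside, 4500.0, 1500.0)
    raster = ElevationRaster(values, xll=lon_min, yll=lat_min, cellsize=cell)

    # Water: equal-area squares on a disjoint slot grid (0.5 deg latitude
    # slots, 1 deg longitude columns) so the summed area is exact by
    # construction.  Corridor squares sit east of the geodesic along the
    # detour bump; background squares sit west of it.
    n_squares = max(1, int(round(cfg.water_total_area_km2 / (18.0 * 18.0))))
    side_km = math.sqrt(cfg.water_total_area_km2 / n_squares)  # n * side^2 exact
    n_corridor = int(round(cfg.water_on_detour_fraction * n_squares))
    mean_amp = float(np.mean(list(cfg.detour_amplitude_mean_km.values())))
    slot_step, n_slots = 0.5, 16
    polys, labels = [], []
    for i in range(n_squares):
        on_corridor = i < n_corridor
        slot = i % n_slots
        column = i // n_slots
        lat_c = cfg.detour_peak_lat - 4.0 + slot_step * slot
        base_lon = _geodesic_lon_at(cfg.origin, cfg.destination, lat_c)
        if on_corridor:
            shift = mean_amp * 0.5 * (
                1.0 + np.cos(np.pi * (lat_c - cfg.detour_peak_lat) / cfg.detour_halfwidth_deg)
            )
            lon_c = base_lon + shift / (KM_PER_DEGREE * math.cos(math.radians(lat_c))) + column
        else:
            # background water just west of the geodesic, inside a 100-km
            # corridor around the shortest route
            lon_c = base_lon - 0.8 - 0.3 * column
        dlat = side_km / KM_PER_DEGREE
        dlon = side_km / (KM_PER_DEGREE * math.cos(math.radians(lat_c)))
        polys.append(box(lon_c - dlon / 2, lat_c - dlat / 2, lon_c + dlon / 2, lat_c + dlat / 2))
        labels.append("lake" if rng.random() < 0.7 else "river")
    water = WaterLayer(polys, labels)
    return plateau, water, raster


def simulate_grouped_values(
    n_individuals: int,
    n_repeats: int,
    between_sd: float,
    within_sd: float,
    mean: float = 0.0,
    rng: np.random.Generator | int | None = None,
):
    """Gaussian repeated measures with known variance components.

    Each individual gets a persistent offset ~ N(0, between_sd) plus
    independent N(0, within_sd) noise per repeat, so the expected
    repeatability is between_sd^2 / (between_sd^2 + within_sd^2).  Used
    to validate the ANOVA estimator's parameter recovery.
    """
    from .repeatability import GroupedValues

    rng = np.random.default_rng(rng)
    groups = []
    for i in range(n_individuals):
        offset = rng.normal(0.0, between_sd)
        vals = mean + offset + rng.normal(0.0, within_sd, size=n_repeats)
        groups.append((f"ID{i + 1}", tuple(float(v) for v in vals)))
    return GroupedValues(tuple(groups), variable="simulated")


def _geodesic_lon_at(origin: GeoPoint, destination: GeoPoint, lat: float) -> float:
    from .detours import expected_crossing_lon

    lon = expected_crossing_lon(origin, destination, lat)
    if lon is None:  # parallel outside the geodesic's latitude span
        lon = 0.5 * (origin.lon + destination.lon)
    return lon
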