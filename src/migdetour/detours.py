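"""Detour extent relative to the expected shortest (great-circle) route.

The expected shortest route between the origin and destination sites is
the geodesic, discretized finely enough that its length matches the
great-circle distance to well under 0.05%.  The longitudinal detour at a
test parallel is the great-circle separation between the observed route's
most-deviated crossing longitude and the geodesic's crossing longitude at
that parallel; the latitudinal overshoot is the farthest a route pushes
poleward (or equatorward) beyond a terminal site's latitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodesy import (
    GeoPoint,
    Polyline,
    crossing_longitudes,
    gc_distance,
    gc_intermediate,
    parallel_separation,
)
from .nullmodel import DEFAULT_LATITUDE_BINS, most_deviated

DEFAULT_SHORTEST_ROUTE_VERTICES = 201


@dataclass(frozen=True)
class BinDeviation:
    latitude: float
    observed_lon: float | None
    expected_lon: float | None
    deviation_km: float | None


@dataclass(frozen=True)
class DetourProfile:
    bins: tuple[BinDeviation, ...]
    max_longitudinal_detour_km: float | None
    max_detour_latitude: float | None
    latitudinal_overshoot_km: float
    additional_km: float | None = None
    additional_pct: float | None = None


def shortest_route(
    origin: GeoPoint, destination: GeoPoint, n_vertices: int = DEFAULT_SHORTEST_ROUTE_VERTICES
) -> Polyline:
    """The geodesic origin->destination discretized at n_vertices points."""
    if n_vertices < 2:
        raise ValueError("n_vertices must be >= 2")
    pts = [gc_intermediate(origin, destination, f) for f in np.linspace(0.0, 1.0, n_vertices)]
    pts[0], pts[-1] = origin, destination  # pin endpoints exactly
    return Polyline(pts)


def expected_crossing_lon(
    origin: GeoPoint, destination: GeoPoint, lat: float,
    n_vertices: int = DEFAULT_SHORTEST_ROUTE_VERTICES,
) -> float | None:
    """Crossing longitude of the discretized geodesic at ``lat``.

    A geodesic crosses a parallel at most twice; between origin and
    destination here it crosses once, so the first crossing is returned.
    """
    crossings = crossing_longitudes(shortest_route(origin, destination, n_vertices), lat)
    return crossings[0] if crossings else None


def deviation_profile(
    observed: Polyline,
    origin: GeoPoint,
    destination: GeoPoint,
    bins=DEFAULT_LATITUDE_BINS,
    overshoot_terminal: GeoPoint | None = None,
    overshoot_direction: str = "poleward",
) -> DetourProfile:
    """Per-parallel longitudinal deviations of an observed route.

    For each test parallel the observed crossing is the most-deviated one
    (relative to the geodesic's crossing there) and the deviation is the
    same-latitude great-circle separation in km.  Parallels the observed
    route never reaches are reported with absent values; the maximum
    deviation over present bins is reported with its latitude.
    """
    expected = shortest_route(origin, destination)
    records: list[BinDeviation] = []
    best_km: float | None = None
    best_lat: float | None = None
    for lat in bins:
        exp_cross = crossing_longitudes(expected, lat)
        exp_lon = exp_cross[0] if exp_cross else None
        obs_cross = crossing_longitudes(observed, lat)
        if exp_lon is None or not obs_cross:
            records.append(BinDeviation(lat, None, exp_lon, None))
            continue
        obs_lon = most_deviated(obs_cross, exp_lon)
        dev = parallel_separation(obs_lon, exp_lon, lat)
        records.append(BinDeviation(lat, obs_lon, exp_lon, dev))
        if best_km is None or dev > best_km:
            best_km, best_lat = dev, lat

    overshoot = 0.0
    if overshoot_terminal is not None:
        overshoot = latitudinal_overshoot(observed, overshoot_terminal, overshoot_direction)

    return DetourProfile(
        bins=tuple(records),
        max_longitudinal_detour_km=best_km,
        max_detour_latitude=best_lat,
        latitudinal_overshoot_km=overshoot,
    )


def latitudinal_overshoot(
    observed: Polyline, terminal: GeoPoint, direction: str = "poleward"
) -> float:
    """Maximum km a route pushes beyond the terminal site's latitude.

    Measured along the meridian at each overshooting vertex's longitude;
    0 when no vertex overshoots.  ``direction`` is "poleward" (beyond the
    terminal away from the equator) or "equatorward".
    """
    if direction not in ("poleward", "equatorward"):
        raise ValueError("direction must be 'poleward' or 'equatorward'")
    t_lat = terminal.lat
    sign = 1.0 if (t_lat >= 0) == (direction == "poleward") else -1.0
    best = 0.0
    for lon, lat in observed.coords:
        if sign * (lat - t_lat) > 0:
            d = gc_distance(GeoPoint(lon, lat), GeoPoint(lon, t_lat))
            best = max(best, d)
    return best


def additional_detour(cumulative_km: float, shortest_km: float) -> tuple[float, float]:
    """Extra distance travelled versus the geodesic, in km and percent."""
    if shortest_km <= 0:
        raise ValueError("shortest_km must be positive")
    if cumulative_km < shortest_km:
        raise ValueError(
            "cumulative distance below the geodesic minimum: upstream metric error"
        )
    extra = cumulative_km - shortest_km
    return extra, 100.0 * extra / shortest_km
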