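"""Journey segmentation and per-journey migration parameters.

A Journey is one individual's filtered fix sequence for one season and
year, travelling between a known origin and destination site.  From it we
derive the standard timing and route parameters: departure and arrival
dates, duration, shortest (great-circle) distance, cumulative route
distance, average speed, straightness index, and the trans-plateau
distance/duration/speed for the portion of the route inside a high-plateau
region polygon.

Departure and arrival are detected with an explicit radius rule rather
than visual inspection: the bird has departed once it permanently leaves a
``site_radius_km`` disc around the origin, and has arrived once it enters
the destination disc for good.  When a transmission gap spans the
transition, the assigned date is the median (midpoint, rounded down to
whole days) of the flanking fix dates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, MultiPolygon, Point, Polygon, shape
from shapely.geometry.base import BaseGeometry

from .argos import Fix
from .geodesy import GeoPoint, Polyline, gc_distance, path_length

DEFAULT_SITE_RADIUS_KM = 25.0


class IncompleteJourneyError(ValueError):
    """The track never leaves the origin or never settles at the destination."""


@dataclass(frozen=True)
class Journey:
    animal_id: str
    season: str  # "autumn" | "spring"
    year: int
    fixes: tuple[Fix, ...]
    origin: GeoPoint
    destination: GeoPoint

    def __post_init__(self) -> None:
        if self.season not in ("autumn", "spring"):
            raise ValueError(f"season must be autumn or spring, got {self.season!r}")
        if len(self.fixes) < 2:
            raise ValueError("a Journey needs at least 2 fixes")
        if self.origin.as_tuple() == self.destination.as_tuple():
            raise ValueError("origin and destination must differ")

    @property
    def label(self) -> str:
        return f"{self.animal_id}-{self.season}-{self.year}"

    def route(self) -> Polyline:
        """Fix positions as a polyline, consecutive duplicates dropped."""
        return _polyline_from_points([f.point.as_tuple() for f in self.fixes])


@dataclass(frozen=True)
class JourneySummary:
    animal_id: str
    season: str
    year: int
    departure_date: date
    arrival_date: date
    duration_days: int
    shortest_km: float
    cumulative_km: float
    speed_km_per_day: float
    straightness: float
    trans_plateau_km: float
    trans_plateau_days: int | None
    trans_plateau_speed: float | None
    mean_altitude_m: float | None


class RegionPolygon:
    """A labelled lon-lat polygon region (e.g. plateau above 3,000 m)."""

    def __init__(self, geometry: BaseGeometry, label: str = ""):
        if geometry.is_empty or not geometry.is_valid:
            raise ValueError("region geometry must be a valid non-empty polygon")
        if geometry.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"unsupported region geometry {geometry.geom_type}")
        self.geometry = geometry
        self.label = label

    @classmethod
    def from_geojson(cls, path: str | Path, label: str = "") -> "RegionPolygon":
        obj = json.loads(Path(path).read_text())
        geoms = _collect_geometries(obj)
        if not geoms:
            raise ValueError(f"{path}: no polygon geometry found")
        merged = geoms[0]
        for g in geoms[1:]:
            merged = merged.union(g)
        return cls(merged, label=label)

    def to_geojson(self, path: str | Path) -> None:
        feature = {
            "type": "Feature",
            "properties": {"label": self.label},
            "geometry": self.geometry.__geo_interface__,
        }
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": [feature]})
        )

    def contains_point(self, p: GeoPoint) -> bool:
        return bool(self.geometry.covers(Point(p.lon, p.lat)))


def _collect_geometries(obj: dict) -> list[BaseGeometry]:
    t = obj.get("type")
    if t == "FeatureCollection":
        out = []
        for feat in obj["features"]:
            out.extend(_collect_geometries(feat))
        return out
    if t == "Feature":
        return _collect_geometries(obj["geometry"])
    if t in ("Polygon", "MultiPolygon"):
        return [shape(obj)]
    return []


class ElevationRaster:
    """Plain-text (ESRI-ASCII-grid style) elevation raster, metres.

    Rows run north to south; cell (0, 0) of ``values`` is the north-west
    corner.  Sampling is nearest-cell.
    """

    def __init__(self, values: np.ndarray, xll: float, yll: float, cellsize: float,
                 nodata: float = -9999.0):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        self.xll = float(xll)
        self.yll = float(yll)
        self.cellsize = float(cellsize)
        self.nodata = float(nodata)

    @classmethod
    def read(cls, path: str | Path) -> "ElevationRaster":
        lines = Path(path).read_text().splitlines()
        header: dict[str, float] = {}
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        values = np.loadtxt(lines[i:], dtype=float, ndmin=2)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("raster grid shape does not match header")
        return cls(values, header["xllcorner"], header["yllcorner"],
                   header["cellsize"], header.get("nodata_value", -9999.0))

    def write(self, path: str | Path) -> None:
        nrows, ncols = self.values.shape
        with Path(path).open("w") as fh:
            fh.write(f"ncols {ncols}\nnrows {nrows}\n")
            fh.write(f"xllcorner {self.xll}\nyllcorner {self.yll}\n")
            fh.write(f"cellsize {self.cellsize}\nnodata_value {self.nodata}\n")
            for row in self.values:
                fh.write(" ".join(f"{v:.1f}" for v in row) + "\n")

    def sample(self, lon: float, lat: float) -> float | None:
        nrows, ncols = self.values.shape
        col = int(math.floor((lon - self.xll) / self.cellsize))
        row = nrows - 1 - int(math.floor((lat - self.yll) / self.cellsize))
        if not (0 <= row < nrows and 0 <= col < ncols):
            return None
        v = self.values[row, col]
        return None if v == self.nodata else float(v)


def _polyline_from_points(points: Sequence[tuple[float, float]]) -> Polyline:
    dedup: list[tuple[float, float]] = []
    for p in points:
        if not dedup or p != dedup[-1]:
            dedup.append(p)
    return Polyline(dedup)


def _median_date(a: date, b: date) -> date:
    """Midpoint of two dates, rounded down to the earlier whole day."""
    if b < a:
        a, b = b, a
    return a + timedelta(days=(b - a).days // 2)


def detect_departure_arrival(
    j: Journey, site_radius_km: float = DEFAULT_SITE_RADIUS_KM
) -> tuple[date, date]:
    """Departure and arrival dates under the radius rule.

    Departure: the bird departs between the last fix within
    ``site_radius_km`` of the origin and the following fix; the assigned
    date is the median of the two flanking fix dates.  Arrival: the bird
    arrives between the last fix outside the destination radius and the
    first fix of its final, uninterrupted stay inside; same median rule.
    """
    dists_o = [gc_distance(f.point, j.origin) for f in j.fixes]
    dists_d = [gc_distance(f.point, j.destination) for f in j.fixes]
    inside_o = [d <= site_radius_km for d in dists_o]
    inside_d = [d <= site_radius_km for d in dists_d]

    if not any(inside_o):
        raise IncompleteJourneyError(f"{j.label}: track never visits the origin site")
    i_dep = max(i for i, w in enumerate(inside_o) if w)
    if i_dep == len(j.fixes) - 1:
        raise IncompleteJourneyError(f"{j.label}: track never leaves the origin site")

    # first index from which every remaining fix is inside the destination
    i_arr = None
    for i in range(len(j.fixes) - 1, -1, -1):
        if inside_d[i]:
            i_arr = i
        else:
            break
    if i_arr is None or i_arr <= i_dep:
        raise IncompleteJourneyError(f"{j.label}: track never settles at the destination site")

    dep = _median_date(j.fixes[i_dep].timestamp.date(), j.fixes[i_dep + 1].timestamp.date())
    arr = _median_date(j.fixes[i_arr - 1].timestamp.date(), j.fixes[i_arr].timestamp.date())
    return dep, arr


def clip_length_in_region(route: Polyline, region: RegionPolygon) -> float:
    """Great-circle length (km) of the parts of ``route`` inside ``region``.

    Boundary crossings are interpolated linearly in lon-lat space, matching
    the planar treatment used for latitude crossings.
    """
    line = LineString(route.coords)
    inter = region.geometry.intersection(line)
    return _geodesic_length_of(inter)


def _geodesic_length_of(geom: BaseGeometry) -> float:
    if geom.is_empty:
        return 0.0
    if geom.geom_type == "LineString":
        coords = list(geom.coords)
        if len(coords) < 2:
            return 0.0
        return path_length(Polyline(_dedup(coords)))
    if geom.geom_type in ("MultiLineString", "GeometryCollection"):
        return sum(_geodesic_length_of(g) for g in geom.geoms)
    return 0.0  # points etc. carry no length


def _dedup(coords):
    out = []
    for c in coords:
        t = (float(c[0]), float(c[1]))
        if not out or t != out[-1]:
            out.append(t)
    if len(out) == 1:
        out.append(out[0])  # will be rejected upstream; defensive
    return out


def _plateau_dates(j: Journey, region: RegionPolygon) -> tuple[date, date] | None:
    inside = [region.contains_point(f.point) for f in j.fixes]
    if not any(inside):
        return None
    first_in = inside.index(True)
    last_in = len(inside) - 1 - inside[::-1].index(True)
    if first_in > 0:
        entry = _median_date(j.fixes[first_in - 1].timestamp.date(),
                             j.fixes[first_in].timestamp.date())
    else:
        entry = j.fixes[first_in].timestamp.date()
    if last_in < len(j.fixes) - 1:
        exit_ = _median_date(j.fixes[last_in].timestamp.date(),
                             j.fixes[last_in + 1].timestamp.date())
    else:
        exit_ = j.fixes[last_in].timestamp.date()
    return entry, exit_


def summarize(
    j: Journey,
    plateau: RegionPolygon | None = None,
    elevation: ElevationRaster | None = None,
    site_radius_km: float = DEFAULT_SITE_RADIUS_KM,
) -> JourneySummary:
    """All Table-1-style parameters for one journey.

    ``shortest_km`` is the great-circle origin-destination distance,
    ``cumulative_km`` the route length between the departure and arrival
    fixes, speed their ratio over whole days, and straightness
    shortest/cumulative.  Trans-plateau metrics cover the route portion
    inside ``plateau``; mean altitude is the mean of ``elevation`` sampled
    at route vertices when a raster is given.
    """
    dep, arr = detect_departure_arrival(j, site_radius_km)
    duration = max(1, (arr - dep).days)

    dists_o = [gc_distance(f.point, j.origin) for f in j.fixes]
    i_dep = max(i for i, d in enumerate(dists_o) if d <= site_radius_km)
    dists_d = [gc_distance(f.point, j.destination) for f in j.fixes]
    i_arr = len(j.fixes) - 1
    while i_arr > 0 and dists_d[i_arr - 1] <= site_radius_km:
        i_arr -= 1

    route = _polyline_from_points(
        [f.point.as_tuple() for f in j.fixes[i_dep:i_arr + 1]]
    )
    shortest = gc_distance(j.origin, j.destination)
    cumulative = path_length(route)
    straightness = min(1.0, shortest / cumulative) if cumulative > 0 else 1.0

    trans_km = 0.0
    trans_days: int | None = None
    trans_speed: float | None = None
    if plateau is not None:
        trans_km = clip_length_in_region(route, plateau)
        span = _plateau_dates(j, plateau)
        if span is not None and trans_km > 0:
            trans_days = max(1, (span[1] - span[0]).days)
            trans_speed = trans_km / trans_days

    mean_alt: float | None = None
    if elevation is not None:
        samples = [elevation.sample(lon, lat) for lon, lat in route.coords]
        vals = [s for s in samples if s is not None]
        if vals:
            mean_alt = float(np.mean(vals))

    return JourneySummary(
        animal_id=j.animal_id,
        season=j.season,
        year=j.year,
        departure_date=dep,
        arrival_date=arr,
        duration_days=duration,
        shortest_km=shortest,
        cumulative_km=cumulative,
        speed_km_per_day=cumulative / duration,
        straightness=straightness,
        trans_plateau_km=trans_km,
        trans_plateau_days=trans_days,
        trans_plateau_speed=trans_speed,
        mean_altitude_m=mean_alt,
    )


def aggregate_summaries(per_individual_means: Sequence[tuple[float, int]]) -> float:
    """Journey-count-weighted pooled mean of per-individual means.

    This is the arithmetic behind an "all birds" column: each individual
    contributes its mean weighted by its number of journeys.
    """
    if not per_individual_means:
        raise ValueError("no per-individual means to aggregate")
    total_n = sum(n for _, n in per_individual_means)
    if total_n <= 0:
        raise ValueError("journey counts must be positive")
    return sum(m * n for m, n in per_individual_means) / total_n


def summaries_to_frame(summaries: Sequence[JourneySummary]):
    """JourneySummary records as a pandas DataFrame (one row per journey)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "season": s.season,
                "year": s.year,
                "departure_date": s.departure_date.isoformat(),
                "arrival_date": s.arrival_date.isoformat(),
                "duration_days": s.duration_days,
                "shortest_km": s.shortest_km,
                "cumulative_km": s.cumulative_km,
                "speed_km_per_day": s.speed_km_per_day,
                "straightness": s.straightness,
                "trans_plateau_km": s.trans_plateau_km,
                "trans_plateau_days": s.trans_plateau_days,
                "trans_plateau_speed": s.trans_plateau_speed,
                "mean_altitude_m": s.mean_altitude_m,
            }
            for s in summaries
        ]
    )
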