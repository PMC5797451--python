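"""Water-body proximity within buffer corridors around routes.

"Proximity to water" is the percent of a corridor's area covered by water
polygons.  The corridor is the set of points within ``width_km`` of the
route polyline, computed in a local azimuthal-equidistant projection
centred on the route's midpoint: over the few-thousand-km extents involved
the projection's area distortion at 100-km buffer scales is far below the
reporting precision.  Each journey's observed corridor is compared with
the corridor around the expected shortest (geodesic) route between the
same endpoints; the paired difference is the habitat-association signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, MultiPolygon, Polygon, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .geodesy import EARTH_RADIUS_KM, GeoPoint, Polyline
from .detours import shortest_route
from .journeys import Journey

DEFAULT_BUFFER_KM = 100.0


class LocalProjection:
    """Azimuthal-equidistant projection on the sphere, in km.

    Distances and azimuths from the centre are exact; area distortion
    grows only with the fourth power of distance from the centre.
    """

    def __init__(self, center_lon: float, center_lat: float):
        self.lon0 = math.radians(center_lon)
        self.lat0 = math.radians(center_lat)

    def forward(self, lons, lats) -> tuple[np.ndarray, np.ndarray]:
        lam = np.radians(np.asarray(lons, dtype=float))
        phi = np.radians(np.asarray(lats, dtype=float))
        dlam = lam - self.lon0
        cos_c = np.sin(self.lat0) * np.sin(phi) + np.cos(self.lat0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), with the centre's removable singularity filled in
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(self.lat0) * np.sin(phi) - np.sin(self.lat0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def project_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        if geom.geom_type == "Polygon":
            ext = self._ring(geom.exterior.coords)
            ints = [self._ring(r.coords) for r in geom.interiors]
            return Polygon(ext, ints)
        if geom.geom_type == "MultiPolygon":
            return MultiPolygon([self.project_geometry(g) for g in geom.geoms])
        if geom.geom_type == "LineString":
            return LineString(self._ring(geom.coords))
        raise ValueError(f"unsupported geometry {geom.geom_type}")

    def _ring(self, coords):
        arr = np.asarray(coords, dtype=float)
        x, y = self.forward(arr[:, 0], arr[:, 1])
        return list(zip(x, y))


@dataclass(frozen=True)
class HabitatComparison:
    journey_label: str
    observed_water_pct: float
    shortest_water_pct: float
    buffer_width_km: float

    @property
    def difference_pct(self) -> float:
        return self.observed_water_pct - self.shortest_water_pct


class WaterLayer:
    """Lake and river polygons in lon-lat degrees."""

    def __init__(self, polygons: Sequence[BaseGeometry], labels: Sequence[str] | None = None):
        polys: list[BaseGeometry] = []
        for g in polygons:
            if g.geom_type not in ("Polygon", "MultiPolygon"):
                raise ValueError(f"water layer needs polygons, got {g.geom_type}")
            if not g.is_valid:
                raise ValueError("invalid water polygon")
            polys.append(g)
        self.polygons = list(polys)
        self.labels = list(labels) if labels is not None else ["water"] * len(polys)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "WaterLayer":
        obj = json.loads(Path(path).read_text())
        feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
        geoms, labels = [], []
        for f in feats:
            geom = shape(f["geometry"] if f.get("type") == "Feature" else f)
            props = f.get("properties") or {}
            geoms.append(geom)
            labels.append(props.get("label", "water"))
        return cls(geoms, labels)

    def to_geojson(self, path: str | Path) -> None:
        feats = [
            {
                "type": "Feature",
                "properties": {"label": lbl},
                "geometry": g.__geo_interface__,
            }
            for g, lbl in zip(self.polygons, self.labels)
        ]
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))

    def merged(self) -> BaseGeometry:
        return unary_union(self.polygons)

    def total_area_km2(self, projection: LocalProjection) -> float:
        return self.projection_area(self.merged(), projection)

    @staticmethod
    def projection_area(geom: BaseGeometry, projection: LocalProjection) -> float:
        return projection.project_geometry(geom).area


def _route_projection(route: Polyline) -> LocalProjection:
    mid = route.coords[len(route) // 2]
    return LocalProjection(float(mid[0]), float(mid[1]))


def buffer_route(
    route: Polyline, width_km: float = DEFAULT_BUFFER_KM,
    projection: LocalProjection | None = None,
) -> tuple[BaseGeometry, LocalProjection]:
    """Corridor polygon within ``width_km`` of the route, in projected km.

    Returns the (projected) buffer polygon together with the projection
    used, so water layers can be intersected in the same plane.
    """
    if width_km <= 0:
        raise ValueError("buffer width must be positive")
    proj = projection or _route_projection(route)
    x, y = proj.forward(route.coords[:, 0], route.coords[:, 1])
    line = LineString(list(zip(x, y)))
    buf = line.buffer(width_km, quad_segs=32)
    if buf.is_empty or buf.area <= 0:
        raise ValueError("degenerate route: empty buffer")
    return buf, proj


def water_fraction(
    buffer_geom: BaseGeometry, water: WaterLayer, projection: LocalProjection
) -> float:
    """Percent of the corridor covered by water polygons."""
    merged = projection.project_geometry(water.merged()) if water.polygons else None
    if merged is None or merged.is_empty:
        return 0.0
    inter = buffer_geom.intersection(merged)
    return 100.0 * inter.area / buffer_geom.area


def compare_routes(
    journeys: Sequence[Journey],
    water: WaterLayer,
    width_km: float = DEFAULT_BUFFER_KM,
    clip_region: BaseGeometry | None = None,
) -> tuple[list[HabitatComparison], float]:
    """Observed vs expected-shortest water cover per journey.

    Returns per-journey comparisons and the paired mean difference
    (observed minus shortest) in percentage points.  An optional
    ``clip_region`` (lon-lat polygon) restricts both routes to that
    region before buffering.
    """
    if not journeys:
        raise ValueError("no journeys to compare")
    out: list[HabitatComparison] = []
    for j in journeys:
        obs = j.route()
        exp = shortest_route(j.origin, j.destination)
        if clip_region is not None:
            obs = _clip_route(obs, clip_region) or obs
            exp = _clip_route(exp, clip_region) or exp
        obs_buf, proj = buffer_route(obs, width_km)
        exp_buf, _ = buffer_route(exp, width_km, projection=proj)
        out.append(
            HabitatComparison(
                journey_label=j.label,
                observed_water_pct=water_fraction(obs_buf, water, proj),
                shortest_water_pct=water_fraction(exp_buf, water, proj),
                buffer_width_km=width_km,
            )
        )
    mean_diff = float(np.mean([c.difference_pct for c in out]))
    return out, mean_diff


def _clip_route(route: Polyline, region: BaseGeometry) -> Polyline | None:
    inter = region.intersection(LineString(route.coords))
    if inter.is_empty:
        return None
    if inter.geom_type == "LineString":
        coords = list(inter.coords)
    elif inter.geom_type in ("MultiLineString", "GeometryCollection"):
        parts = [g for g in inter.geoms if g.geom_type == "LineString"]
        if not parts:
            return None
        coords = list(max(parts, key=lambda g: g.length).coords)
    else:
        return None
    if len(coords) < 2:
        return None
    dedup = []
    for c in coords:
        t = (float(c[0]), float(c[1]))
        if not dedup or t != dedup[-1]:
            dedup.append(t)
    return Polyline(dedup) if len(dedup) >= 2 else None
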