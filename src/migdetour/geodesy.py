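"""Spherical-earth geometry primitives.

All routes are polylines of (lon, lat) vertices in decimal degrees on a
sphere of radius ``EARTH_RADIUS_KM``.  Latitude-crossing interpolation is
deliberately linear in lon-lat (plate carrée) space: route segments in the
study system are at most a few degrees long, where the difference from the
true geodesic crossing is negligible, and it keeps the segment-permutation
null model exactly endpoint-preserving.

The antimeridian is out of scope: longitudes live in [-180, 180) and no
segment may span more than 180 degrees of longitude.  Violations raise
rather than wrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Mean earth radius (IUGG), kilometres.
EARTH_RADIUS_KM = 6371.0088

#: Kilometres per degree of great-circle arc.
KM_PER_DEGREE = 2.0 * math.pi * EARTH_RADIUS_KM / 360.0


class GeodesyError(ValueError):
    """Invalid coordinates or degenerate geometry."""


@dataclass(frozen=True)
class GeoPoint:
    """A longitude/latitude position in decimal degrees.

    lon is degrees east in [-180, 180); lat is degrees north in [-90, 90].
    """

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise GeodesyError(f"non-finite coordinates ({self.lon}, {self.lat})")
        if not -90.0 <= self.lat <= 90.0:
            raise GeodesyError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon < 180.0:
            raise GeodesyError(f"longitude {self.lon} outside [-180, 180)")

    def as_tuple(self) -> tuple[float, float]:
        return (self.lon, self.lat)


class Polyline:
    """An ordered route of >= 2 GeoPoint vertices.

    Consecutive vertices must differ and no segment may span the
    antimeridian.  Internally stores a float array of shape (n, 2)
    with columns (lon, lat).
    """

    __slots__ = ("coords",)

    def __init__(self, vertices: Iterable[GeoPoint | Sequence[float]]):
        pts = []
        for v in vertices:
            if isinstance(v, GeoPoint):
                pts.append(v.as_tuple())
            else:
                pts.append(GeoPoint(float(v[0]), float(v[1])).as_tuple())
        if len(pts) < 2:
            raise GeodesyError("a Polyline needs at least 2 vertices")
        arr = np.asarray(pts, dtype=float)
        dif = np.diff(arr, axis=0)
        if np.any(np.all(dif == 0.0, axis=1)):
            raise GeodesyError("consecutive vertices must not be identical")
        if np.any(np.abs(dif[:, 0]) > 180.0):
            raise GeodesyError("segment spans the antimeridian")
        self.coords = arr

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i: int) -> GeoPoint:
        lon, lat = self.coords[i]
        return GeoPoint(float(lon), float(lat))

    def __iter__(self):
        for lon, lat in self.coords:
            yield GeoPoint(float(lon), float(lat))

    @property
    def start(self) -> GeoPoint:
        return self[0]

    @property
    def end(self) -> GeoPoint:
        return self[-1]


def _as_lonlat(p) -> tuple[float, float]:
    if isinstance(p, GeoPoint):
        return p.lon, p.lat
    lon, lat = float(p[0]), float(p[1])
    GeoPoint(lon, lat)  # validate
    return lon, lat


def gc_distance(a, b) -> float:
    """Great-circle distance in km between two points (haversine).

    Symmetric, non-negative, zero iff the points coincide.
    """
    lon1, lat1 = _as_lonlat(a)
    lon2, lat2 = _as_lonlat(b)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _gc_distance_arrays(lon1, lat1, lon2, lat2):
    """Vectorised haversine on degree arrays; returns km."""
    phi1 = np.radians(lat1)
    phi2 = np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def path_length(route: Polyline) -> float:
    """Total great-circle length of a route in km (sum over segments)."""
    c = route.coords
    return float(np.sum(_gc_distance_arrays(c[:-1, 0], c[:-1, 1], c[1:, 0], c[1:, 1])))


def _to_unit_vector(lon: float, lat: float) -> np.ndarray:
    lam, phi = math.radians(lon), math.radians(lat)
    return np.array(
        [math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)]
    )


def _from_unit_vector(v: np.ndarray) -> GeoPoint:
    lon = math.degrees(math.atan2(v[1], v[0]))
    lat = math.degrees(math.asin(max(-1.0, min(1.0, v[2]))))
    if lon >= 180.0:
        lon -= 360.0
    return GeoPoint(lon, lat)


def gc_intermediate(a, b, f: float) -> GeoPoint:
    """Point a fraction ``f`` of the way from a to b along the great circle.

    Spherical linear interpolation; f=0 gives a, f=1 gives b.  Antipodal
    endpoints are rejected (the connecting great circle is ambiguous).
    """
    if not 0.0 <= f <= 1.0:
        raise GeodesyError(f"fraction {f} outside [0, 1]")
    lon1, lat1 = _as_lonlat(a)
    lon2, lat2 = _as_lonlat(b)
    if (lon1, lat1) == (lon2, lat2):
        raise GeodesyError("gc_intermediate requires distinct endpoints")
    u, v = _to_unit_vector(lon1, lat1), _to_unit_vector(lon2, lat2)
    dot = float(np.dot(u, v))
    if dot < -1.0 + 1e-12:
        raise GeodesyError("antipodal endpoints: great circle is ambiguous")
    omega = math.acos(max(-1.0, min(1.0, dot)))
    if omega == 0.0:
        return GeoPoint(lon1, lat1)
    s = math.sin(omega)
    w = (math.sin((1.0 - f) * omega) / s) * u + (math.sin(f * omega) / s) * v
    return _from_unit_vector(w / np.linalg.norm(w))


def crossing_longitudes(route: Polyline, lat: float) -> list[float]:
    """Longitudes where the route crosses the parallel ``lat``.

    One entry per segment whose endpoint latitudes straddle (or touch)
    ``lat``, by linear interpolation in lon-lat space, in travel order.
    A segment ending exactly on the parallel contributes at its endpoint;
    the subsequent segment starting there does not double-count.
    Returns an empty list when the route never reaches ``lat``.
    """
    c = route.coords
    out: list[float] = []
    at_shared_vertex = False  # previous segment already emitted this vertex
    for i in range(c.shape[0] - 1):
        lo1, la1 = c[i]
        lo2, la2 = c[i + 1]
        d1, d2 = la1 - lat, la2 - lat
        if d1 * d2 > 0.0:
            at_shared_vertex = False
            continue
        if d1 == 0.0 and d2 == 0.0:  # segment lies along the parallel
            t, lon = 0.0, lo1
        else:
            t = d1 / (d1 - d2)
            lon = lo1 + t * (lo2 - lo1)
        if t == 0.0 and at_shared_vertex:
            at_shared_vertex = d2 == 0.0
            continue  # vertex on the parallel counted by the previous segment
        out.append(float(lon))
        at_shared_vertex = d2 == 0.0
    return out


def parallel_separation(lon1: float, lon2: float, lat: float) -> float:
    """Great-circle km between two points on the same parallel."""
    return gc_distance(GeoPoint(lon1, lat), GeoPoint(lon2, lat))


def turning_angle(a, b, c) -> float:
    """Internal angle at b of the spherical track a->b->c, in degrees.

    180 means straight-through travel; small angles mean a sharp
    out-and-back spike.  Computed from great-circle bearings at b.
    """
    lon_b, lat_b = _as_lonlat(b)
    az_in = _bearing(lon_b, lat_b, *_as_lonlat(a))
    az_out = _bearing(lon_b, lat_b, *_as_lonlat(c))
    ang = abs(az_in - az_out) % 360.0
    return 360.0 - ang if ang > 180.0 else ang


def _bearing(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dlam = math.radians(lon2 - lon1)
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return math.degrees(math.atan2(y, x)) % 360.0
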