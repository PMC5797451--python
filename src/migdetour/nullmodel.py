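"""Segment-permutation route randomization and the percentile crossing test.

The null model asks whether a route's crossing longitude at a given
parallel is more deviated than chance would produce, given the route's own
step structure.  A randomized route keeps the observed multiset of
lon-lat displacement vectors but shuffles their order uniformly; because
vector addition commutes, every randomization starts and ends exactly at
the observed endpoints.  For each of ``n`` randomized routes we record the
most-deviated crossing longitude at the test parallel (routes that never
cross contribute nothing), and place the observed crossing in that null
distribution with a mid-rank percentile: significant when it falls below
2.5% or above 97.5% (two-tailed, alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodesy import Polyline

#: Test parallels: every 3 degrees from 23N to 44N.
DEFAULT_LATITUDE_BINS = (23.0, 26.0, 29.0, 32.0, 35.0, 38.0, 41.0, 44.0)
DEFAULT_N_RANDOM = 1000


@dataclass(frozen=True)
class NullTestResult:
    latitude: float
    observed_lon: float | None
    percentile: float | None
    significant: bool
    n_random: int
    n_noncrossing: int = 0


def route_to_segments(route: Polyline) -> np.ndarray:
    """Displacement vectors (dlon, dlat) per segment, shape (n-1, 2)."""
    return np.diff(route.coords, axis=0)


def segments_to_route(start: tuple[float, float], segments: np.ndarray) -> Polyline:
    """Rebuild a polyline from a start point and displacement vectors."""
    verts = np.vstack([np.asarray(start, dtype=float), segments]).cumsum(axis=0)
    return Polyline(verts)


def randomize_route(route: Polyline, rng: np.random.Generator | int | None = None) -> Polyline:
    """One uniform segment permutation of ``route``.

    Preserves the start and end vertices exactly, the vertex count, and
    the multiset of displacement vectors.
    """
    rng = np.random.default_rng(rng)
    segs = route_to_segments(route)
    if segs.shape[0] < 2:
        return route
    perm = rng.permutation(segs.shape[0])
    verts = np.vstack([route.coords[:1], segs[perm]]).cumsum(axis=0)
    verts[-1] = route.coords[-1]  # exact by permutation invariance; pin rounding
    return Polyline(verts)


def _crossings_matrix(vertices: np.ndarray, lat: float, reference_lon: float) -> np.ndarray:
    """Most-deviated crossing longitude per route, NaN when never crossing.

    ``vertices`` has shape (m, k, 2); linear lon-lat interpolation at the
    parallel, then the crossing farthest from ``reference_lon`` per route
    (ties toward earlier travel order).
    """
    lons = vertices[:, :, 0]
    lats = vertices[:, :, 1]
    d1 = lats[:, :-1] - lat
    d2 = lats[:, 1:] - lat
    cross = (d1 * d2) <= 0.0
    degenerate = (d1 == 0.0) & (d2 == 0.0)
    denom = np.where(d1 - d2 == 0.0, 1.0, d1 - d2)
    t = np.where(degenerate, 0.0, d1 / denom)
    clon = lons[:, :-1] + t * (lons[:, 1:] - lons[:, :-1])
    dev = np.where(cross, np.abs(clon - reference_lon), -np.inf)
    best = np.argmax(dev, axis=1)
    rows = np.arange(vertices.shape[0])
    out = clon[rows, best]
    out[~cross.any(axis=1)] = np.nan
    return out


def null_crossing_distribution(
    route: Polyline,
    lat: float,
    n: int = DEFAULT_N_RANDOM,
    reference_lon: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, int]:
    """Most-deviated crossing longitudes of ``n`` randomized routes at ``lat``.

    Returns ``(crossing_lons, n_noncrossing)``: randomized routes that never
    reach the parallel are dropped from the distribution and counted.
    All ``n`` permutations are drawn as one batch, so a fixed ``rng`` seed
    gives a bit-reproducible distribution.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty(0), 0
    rng = np.random.default_rng(rng)
    segs = route_to_segments(route)
    m = segs.shape[0]
    perms = np.argsort(rng.random((n, m)), axis=1)  # n independent uniform permutations
    shuffled = segs[perms]  # (n, m, 2)
    starts = np.broadcast_to(route.coords[0], (n, 1, 2))
    verts = np.concatenate([starts, shuffled], axis=1).cumsum(axis=1)
    verts[:, -1, :] = route.coords[-1]
    crossings = _crossings_matrix(verts, lat, reference_lon)
    keep = ~np.isnan(crossings)
    return crossings[keep], int(n - keep.sum())


def most_deviated(crossings, reference_lon: float) -> float | None:
    """The crossing longitude farthest from ``reference_lon``.

    Ties break toward the first in travel order; None for no crossings.
    """
    best = None
    best_dev = -1.0
    for c in crossings:
        d = abs(c - reference_lon)
        if d > best_dev:
            best, best_dev = float(c), d
    return best


def percentile_test(
    observed_lon: float,
    null_lons,
    alpha: float = 0.05,
    latitude: float = float("nan"),
    n_noncrossing: int = 0,
) -> NullTestResult:
    """Two-tailed mid-rank percentile placement of the observed crossing.

    percentile = 100 * (#null < observed + 0.5 * #null == observed) / n;
    significant when outside [100*alpha/2, 100*(1 - alpha/2)].
    """
    null_lons = np.asarray(null_lons, dtype=float)
    if null_lons.size == 0:
        raise ValueError("empty null distribution")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = null_lons.size
    pct = 100.0 * (np.sum(null_lons < observed_lon) + 0.5 * np.sum(null_lons == observed_lon)) / n
    lo, hi = 100.0 * alpha / 2.0, 100.0 * (1.0 - alpha / 2.0)
    return NullTestResult(
        latitude=latitude,
        observed_lon=float(observed_lon),
        percentile=float(pct),
        significant=bool(pct < lo or pct > hi),
        n_random=int(n),
        n_noncrossing=int(n_noncrossing),
    )


def no_crossing_result(latitude: float, n_random: int, n_noncrossing: int = 0) -> NullTestResult:
    """Result placeholder for a parallel the observed route never reaches."""
    return NullTestResult(
        latitude=latitude,
        observed_lon=None,
        percentile=None,
        significant=False,
        n_random=n_random,
        n_noncrossing=n_noncrossing,
    )
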