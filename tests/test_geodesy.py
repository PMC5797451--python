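import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from migdetour import (
    EARTH_RADIUS_KM,
    GeoPoint,
    GeodesyError,
    Polyline,
    crossing_longitudes,
    gc_distance,
    gc_intermediate,
    parallel_separation,
    path_length,
)

QUARTER_EQUATOR_KM = math.pi * EARTH_RADIUS_KM / 2.0  # closed form
ONE_DEGREE_KM = 2.0 * math.pi * EARTH_RADIUS_KM / 360.0

lonlat = st.tuples(
    st.floats(min_value=-179.0, max_value=179.0),
    st.floats(min_value=-85.0, max_value=85.0),
)


class TestGeoPoint:
    def test_bounds_enforced(self):
        with pytest.raises(GeodesyError):
            GeoPoint(0.0, 95.0)
        with pytest.raises(GeodesyError):
            GeoPoint(200.0, 0.0)
        with pytest.raises(GeodesyError):
            GeoPoint(float("nan"), 0.0)

    def test_polyline_rejects_duplicates_and_antimeridian_spans(self):
        with pytest.raises(GeodesyError):
            Polyline([(0, 0), (0, 0)])
        with pytest.raises(GeodesyError):
            Polyline([(-179.0, 0.0), (179.0, 0.0)])
        with pytest.raises(GeodesyError):
            Polyline([(0, 0)])


class TestGcDistance:
    def test_identity_is_zero(self):
        assert gc_distance(GeoPoint(10, 20), GeoPoint(10, 20)) == 0.0

    def test_quarter_equatorial_arc_closed_form(self):
        d = gc_distance(GeoPoint(0, 0), GeoPoint(90, 0))
        assert d == pytest.approx(QUARTER_EQUATOR_KM, abs=1e-6)

    def test_one_degree_meridian_closed_form(self):
        d = gc_distance(GeoPoint(10, 20), GeoPoint(10, 21))
        assert d == pytest.approx(ONE_DEGREE_KM, abs=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(a=lonlat, b=lonlat)
    def test_symmetry(self, a, b):
        assert gc_distance(a, b) == pytest.approx(gc_distance(b, a), abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(a=lonlat, b=lonlat, c=lonlat)
    def test_triangle_inequality(self, a, b, c):
        assert gc_distance(a, c) <= gc_distance(a, b) + gc_distance(b, c) + 1e-9


class TestPathLength:
    def test_two_vertex_route_equals_endpoint_distance(self):
        r = Polyline([(100.0, 36.0), (90.0, 22.0)])
        assert path_length(r) == pytest.approx(gc_distance(r.start, r.end))

    def test_out_and_back_doubles(self):
        a, b = (100.0, 36.0), (95.0, 30.0)
        r = Polyline([a, b, a])
        assert path_length(r) == pytest.approx(2.0 * gc_distance(a, b))

    def test_geodesic_sampling_matches_direct_distance(self):
        a, b = GeoPoint(100.2, 36.8), GeoPoint(90.0, 22.0)
        pts = [gc_intermediate(a, b, f) for f in np.linspace(0, 1, 10)]
        assert path_length(Polyline(pts)) == pytest.approx(
            gc_distance(a, b), rel=1e-3
        )


class TestGcIntermediate:
    def test_endpoints(self):
        a, b = GeoPoint(10, 20), GeoPoint(30, 40)
        assert gc_intermediate(a, b, 0.0).as_tuple() == pytest.approx(a.as_tuple())
        assert gc_intermediate(a, b, 1.0).as_tuple() == pytest.approx(b.as_tuple())

    def test_equatorial_midpoint(self):
        p = gc_intermediate(GeoPoint(0, 0), GeoPoint(90, 0), 0.5)
        assert p.lon == pytest.approx(45.0, abs=1e-9)
        assert p.lat == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("f", [0.1, 0.25, 0.5, 0.9])
    def test_fraction_matches_arc_ratio(self, f):
        a, b = GeoPoint(100.2, 36.8), GeoPoint(90.0, 22.0)
        p = gc_intermediate(a, b, f)
        assert gc_distance(a, p) / gc_distance(a, b) == pytest.approx(f, abs=1e-9)

    def test_antipodal_rejected(self):
        with pytest.raises(GeodesyError):
            gc_intermediate(GeoPoint(0, 0), GeoPoint(-180, 0), 0.5)


class TestCrossingLongitudes:
    def test_meridian_route(self):
        r = Polyline([(70.0, 20.0), (70.0, 40.0)])
        assert crossing_longitudes(r, 29.0) == [70.0]

    def test_double_back_gives_two_entries(self):
        r = Polyline([(70.0, 20.0), (72.0, 31.0), (74.0, 27.0), (76.0, 40.0)])
        assert len(crossing_longitudes(r, 29.0)) == 3

    def test_linear_interpolation_oracle(self):
        # (80,28)->(82,32): lat 29 is 1/4 of the way, so lon = 80 + 0.25*2
        r = Polyline([(80.0, 28.0), (82.0, 32.0)])
        assert crossing_longitudes(r, 29.0) == [pytest.approx(80.5)]

    def test_unreached_latitude_empty(self):
        r = Polyline([(70.0, 20.0), (70.0, 25.0)])
        assert crossing_longitudes(r, 29.0) == []

    def test_vertex_on_parallel_counted_once(self):
        r = Polyline([(70.0, 20.0), (71.0, 29.0), (72.0, 40.0)])
        assert crossing_longitudes(r, 29.0) == [pytest.approx(71.0)]

    def test_crossings_within_segment_longitude_range(self, zigzag_route):
        for lat in (23.0, 29.0, 35.0):
            lons = crossing_longitudes(zigzag_route, lat)
            c = zigzag_route.coords
            lo, hi = c[:, 0].min(), c[:, 0].max()
            assert all(lo - 1e-9 <= x <= hi + 1e-9 for x in lons)


class TestParallelSeparation:
    def test_same_longitude_zero(self):
        assert parallel_separation(95.0, 95.0, 30.0) == 0.0

    def test_one_degree_equator(self):
        assert parallel_separation(10.0, 11.0, 0.0) == pytest.approx(ONE_DEGREE_KM)

    def test_shrinks_with_latitude(self):
        assert parallel_separation(10.0, 11.0, 60.0) < parallel_separation(10.0, 11.0, 0.0)
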