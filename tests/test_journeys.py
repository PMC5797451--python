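from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest
from shapely.geometry import box

from migdetour import (
    ElevationRaster,
    Fix,
    GeoPoint,
    IncompleteJourneyError,
    Journey,
    Polyline,
    RegionPolygon,
    aggregate_summaries,
    clip_length_in_region,
    detect_departure_arrival,
    gc_distance,
    path_length,
    summarize,
)

ORIGIN = GeoPoint(100.2, 36.8)
DEST = GeoPoint(90.0, 22.0)


def _fix(lon, lat, day, hour=0):
    return Fix("G1", datetime(2006, 8, day, hour, tzinfo=timezone.utc),
               GeoPoint(lon, lat), "2")


def _journey(fixes, season="autumn"):
    return Journey("G1", season, 2006, tuple(fixes), ORIGIN, DEST)


class TestDepartureArrival:
    def test_gap_uses_median_date(self):
        # last origin fix Aug 1, first en-route fix Aug 11 -> departure Aug 6
        fixes = [
            _fix(100.2, 36.8, 1),
            _fix(97.0, 32.0, 11),
            _fix(93.0, 26.0, 16),
            _fix(90.0, 22.0, 21),
            _fix(90.0, 22.0, 22),
        ]
        dep, arr = detect_departure_arrival(_journey(fixes))
        assert dep == date(2006, 8, 6)

    def test_continuous_fixes_depart_on_leaving_day(self):
        fixes = [
            _fix(100.2, 36.8, 8),
            _fix(100.2, 36.8, 9, hour=2),
            _fix(99.0, 34.0, 9, hour=10),
            _fix(93.0, 26.0, 15),
            _fix(90.0, 22.0, 20),
        ]
        dep, _ = detect_departure_arrival(_journey(fixes))
        assert dep == date(2006, 8, 9)

    def test_arrival_median_of_flanking_dates(self):
        fixes = [
            _fix(100.2, 36.8, 1),
            _fix(95.0, 28.0, 10),
            _fix(90.0, 22.0, 20),  # gap 10 -> 20: arrival Aug 15
            _fix(90.0, 22.0, 21),
        ]
        _, arr = detect_departure_arrival(_journey(fixes))
        assert arr == date(2006, 8, 15)

    def test_never_leaving_origin_is_incomplete(self):
        fixes = [_fix(100.2, 36.8, d) for d in range(1, 5)]
        with pytest.raises(IncompleteJourneyError):
            detect_departure_arrival(_journey(fixes))

    def test_never_reaching_destination_is_incomplete(self):
        fixes = [_fix(100.2, 36.8, 1), _fix(97.0, 30.0, 5), _fix(96.0, 29.0, 9)]
        with pytest.raises(IncompleteJourneyError):
            detect_departure_arrival(_journey(fixes))


class TestSummarize:
    def test_straight_two_leg_journey_straightness_one(self):
        fixes = [
            _fix(100.2, 36.8, 1),
            _fix(90.0, 22.0, 20),
            _fix(90.0, 22.0, 21),
        ]
        s = summarize(_journey(fixes))
        assert s.straightness == pytest.approx(1.0, abs=1e-6)
        assert s.cumulative_km >= s.shortest_km - 1e-6

    def test_straightness_matches_distance_ratio(self):
        fixes = [
            _fix(100.2, 36.8, 1),
            _fix(99.0, 30.0, 8),
            _fix(93.0, 27.0, 14),
            _fix(90.0, 22.0, 20),
            _fix(90.0, 22.0, 21),
        ]
        s = summarize(_journey(fixes))
        assert s.straightness == pytest.approx(s.shortest_km / s.cumulative_km)
        assert s.speed_km_per_day == pytest.approx(s.cumulative_km / s.duration_days)

    def test_route_outside_plateau_gives_zero(self):
        region = RegionPolygon(box(0.0, 0.0, 10.0, 10.0), "elsewhere")
        fixes = [
            _fix(100.2, 36.8, 1),
            _fix(95.0, 28.0, 10),
            _fix(90.0, 22.0, 20),
            _fix(90.0, 22.0, 21),
        ]
        s = summarize(_journey(fixes), plateau=region)
        assert s.trans_plateau_km == 0.0
        assert s.trans_plateau_days is None


class TestClipLength:
    def test_fully_inside_and_outside(self):
        region = RegionPolygon(box(80.0, 20.0, 110.0, 40.0))
        r = Polyline([(100.0, 36.0), (90.0, 22.0)])
        assert clip_length_in_region(r, region) == pytest.approx(path_length(r))
        far = RegionPolygon(box(0.0, 0.0, 10.0, 10.0))
        assert clip_length_in_region(r, far) == 0.0

    def test_half_plane_crossing_halves_length(self):
        # meridian route with a region boundary at its midpoint latitude
        r = Polyline([(95.0, 20.0), (95.0, 30.0)])
        region = RegionPolygon(box(90.0, 25.0, 100.0, 60.0))
        assert clip_length_in_region(r, region) == pytest.approx(
            path_length(r) / 2.0, rel=0.01
        )


class TestAggregate:
    def test_weighted_mean_of_per_individual_means(self):
        pooled = aggregate_summaries([(1815, 4), (1895, 3), (1906, 2), (2116, 3)])
        assert round(pooled) == 1925

    def test_single_individual_and_equal_counts(self):
        assert aggregate_summaries([(1815.0, 4)]) == 1815.0
        assert aggregate_summaries([(10.0, 2), (20.0, 2)]) == 15.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_summaries([])


class TestRasterAndRegion:
    def test_raster_roundtrip_and_sampling(self, tmp_path):
        values = np.array([[4500.0, 1500.0], [2000.0, 3000.0]])
        r = ElevationRaster(values, xll=90.0, yll=30.0, cellsize=1.0)
        p = tmp_path / "dem.asc"
        r.write(p)
        r2 = ElevationRaster.read(p)
        assert np.array_equal(r2.values, values)
        assert r2.sample(90.5, 31.5) == 4500.0  # NW cell
        assert r2.sample(91.5, 30.5) == 3000.0  # SE cell
        assert r2.sample(200.0, 0.0) is None

    def test_region_geojson_roundtrip(self, tmp_path):
        region = RegionPolygon(box(84.0, 26.0, 104.0, 38.0), label="plateau")
        p = tmp_path / "region.geojson"
        region.to_geojson(p)
        back = RegionPolygon.from_geojson(p, label="plateau")
        assert back.geometry.equals(region.geometry)
        assert back.contains_point(GeoPoint(95.0, 30.0))
        assert not back.contains_point(GeoPoint(50.0, 30.0))
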