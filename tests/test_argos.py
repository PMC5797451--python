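import math
from datetime import datetime, timedelta, timezone

import pytest

from migdetour import Fix, FilterConfig, GeoPoint, gc_distance, plausibility_filter, read_fixes, write_fixes
from migdetour.argos import FixParseError, read_filter_config

T0 = datetime(2006, 8, 1, tzinfo=timezone.utc)


def fix(lon, lat, hours, lc="B", animal="G1"):
    return Fix(animal_id=animal, timestamp=T0 + timedelta(hours=hours),
               point=GeoPoint(lon, lat), loc_class=lc)


def spherical_angle_at(b, a, c):
    """Independent oracle: internal angle at b via the spherical law of cosines."""
    R = 6371.0088
    ab = gc_distance(a, b) / R
    bc = gc_distance(b, c) / R
    ac = gc_distance(a, c) / R
    cosang = (math.cos(ac) - math.cos(ab) * math.cos(bc)) / (math.sin(ab) * math.sin(bc))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


class TestReadWrite:
    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("animal_id,timestamp,lon,lat,loc_class\n")
        assert read_fixes(p) == []

    def test_rows_sorted_and_roundtrip(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text(
            "animal_id,timestamp,lon,lat,loc_class\n"
            "G1,2006-08-01T12:00:00+00:00,100.1,36.7,B\n"
            "G1,2006-08-01T04:00:00+00:00,100.2,36.8,2\n"
            "G1,2006-08-01T08:00:00+00:00,100.15,36.75,A\n"
        )
        fixes = read_fixes(p)
        assert [f.timestamp.hour for f in fixes] == [4, 8, 12]
        out = tmp_path / "out.csv"
        write_fixes(fixes, out)
        assert read_fixes(out) == fixes

    def test_duplicate_timestamp_keeps_better_class(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text(
            "animal_id,timestamp,lon,lat,loc_class\n"
            "G1,2006-08-01T04:00:00+00:00,100.2,36.8,B\n"
            "G1,2006-08-01T04:00:00+00:00,100.2,36.8,2\n"
        )
        fixes = read_fixes(p)
        assert len(fixes) == 1 and fixes[0].loc_class == "2"

    def test_missing_column_and_bad_latitude_named(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("animal_id,timestamp,lon,loc_class\nG1,2006-08-01,100,B\n")
        with pytest.raises(FixParseError, match="lat"):
            read_fixes(p)
        p.write_text(
            "animal_id,timestamp,lon,lat,loc_class\nG1,2006-08-01T00:00:00,100,95,B\n"
        )
        with pytest.raises(FixParseError, match="row 2"):
            read_fixes(p)

    def test_filter_config_file(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("max_speed = 80\nmin_spike_angle = 20\nmax_step=50\n"
                     "keep_classes_always = 2,3\n")
        cfg = read_filter_config(p)
        assert cfg.max_speed == 80 and cfg.min_spike_angle == 20
        assert cfg.keep_classes_always == {"2", "3"}


class TestPlausibilityFilter:
    def test_single_fix_retained(self):
        f = fix(100.0, 36.0, 0)
        assert plausibility_filter([f]) == [f]

    def test_speed_rule_removes_impossible_jump(self):
        # ~200 km in 1 h with a 100 km/h ceiling
        fixes = [
            fix(100.0, 36.0, 0, lc="2"),
            fix(100.0, 36.0 + 200.0 / 111.195, 1, lc="B"),
            fix(100.0, 36.05, 2, lc="2"),
        ]
        kept = plausibility_filter(fixes, FilterConfig(max_speed=100.0))
        assert [f.loc_class for f in kept] == ["2", "2"]

    def test_spike_removed_by_angle_rule(self):
        a = GeoPoint(90.0, 30.0)
        b = GeoPoint(90.0 + 150.0 / (111.195 * math.cos(math.radians(30.0))), 30.0)
        c = GeoPoint(90.0 + 1.0 / (111.195 * math.cos(math.radians(30.0))), 30.0)
        assert spherical_angle_at(b, a, c) < 15.0  # oracle confirms a spike
        fixes = [
            Fix("G1", T0, a, "2"),
            Fix("G1", T0 + timedelta(hours=10), b, "B"),
            Fix("G1", T0 + timedelta(hours=20), c, "2"),
        ]
        kept = plausibility_filter(
            fixes, FilterConfig(max_speed=1000.0, min_spike_angle=15.0, max_step=100.0)
        )
        assert [f.point.lon for f in kept] == [a.lon, c.lon]

    def test_high_quality_classes_never_removed(self):
        fixes = [
            fix(100.0, 36.0, 0, lc="2"),
            fix(100.0, 36.0 + 200.0 / 111.195, 1, lc="3"),
            fix(100.0, 36.05, 2, lc="2"),
        ]
        kept = plausibility_filter(fixes, FilterConfig(max_speed=100.0))
        assert kept == fixes

    def test_first_and_last_always_retained(self):
        fixes = [
            fix(100.0, 36.0, 0, lc="B"),
            fix(100.0, 36.0 + 300.0 / 111.195, 1, lc="B"),
        ]
        kept = plausibility_filter(fixes, FilterConfig(max_speed=1.0))
        assert kept == fixes

    def test_idempotent_and_subsequence(self, small_sim_config):
        from migdetour import simulate_population

        journeys, _ = simulate_population(small_sim_config)
        cfg = FilterConfig()
        for sj in journeys[:4]:
            once = plausibility_filter(sj.journey.fixes, cfg)
            assert plausibility_filter(once, cfg) == once
            it = iter(sj.journey.fixes)
            assert all(f in it for f in once)  # order-preserving subsequence

    def test_permissive_config_is_identity(self, small_sim_config):
        from migdetour import simulate_population

        journeys, _ = simulate_population(small_sim_config)
        cfg = FilterConfig(max_speed=float("inf"), min_spike_angle=0.0)
        fixes = list(journeys[0].journey.fixes)
        assert plausibility_filter(fixes, cfg) == fixes

    def test_unsorted_input_rejected(self):
        fixes = [fix(100.0, 36.0, 5), fix(100.0, 36.1, 0)]
        with pytest.raises(ValueError, match="sorted"):
            plausibility_filter(fixes)
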