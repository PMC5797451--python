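"""Reading, writing and plausibility-filtering of Doppler telemetry fixes.

A fix table is a CSV with columns ``animal_id, timestamp, lon, lat,
loc_class``; timestamps are ISO-8601 UTC.  The plausibility filter is a
simplified distance-rate-angle screen in the spirit of the hybrid filters
used for Argos data: a fix is dropped when the speed implied from the
previously retained fix is impossible, or when it forms a sharp long-legged
spike.  High-accuracy location classes (1-3, with assigned error radii of
150-1,000 m) are never removed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

from .geodesy import GeoPoint, gc_distance, turning_angle

LOC_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")
#: Ordering for duplicate-timestamp resolution: best class first.
_CLASS_RANK = {c: i for i, c in enumerate(LOC_CLASSES)}

REQUIRED_COLUMNS = ("animal_id", "timestamp", "lon", "lat", "loc_class")


class FixParseError(ValueError):
    """A fix table row or header could not be parsed."""


@dataclass(frozen=True)
class Fix:
    """One timestamped Doppler location with an Argos quality class."""

    animal_id: str
    timestamp: datetime
    point: GeoPoint
    loc_class: str

    def __post_init__(self) -> None:
        if self.loc_class not in _CLASS_RANK:
            raise FixParseError(f"unknown location class {self.loc_class!r}")
        if self.timestamp.tzinfo is None:
            object.__setattr__(self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the distance-rate-angle plausibility filter.

    max_speed
        Maximum plausible sustained speed, km/h.  Fixes implying a faster
        leg from the previously retained fix are dropped.
    min_spike_angle
        Fixes forming an internal turning angle sharper than this (degrees)
        are spike candidates.
    max_step
        A spike is only removed when both adjacent steps exceed this many
        km (a sharp turn between nearby fixes is ordinary behaviour).
    keep_classes_always
        Location classes exempt from removal (default the accuracy-assigned
        classes 1-3).
    """

    max_speed: float = 100.0
    min_spike_angle: float = 15.0
    max_step: float = 100.0
    keep_classes_always: frozenset[str] = field(default_factory=lambda: frozenset({"1", "2", "3"}))

    def __post_init__(self) -> None:
        if not self.max_speed > 0:
            raise ValueError("max_speed must be positive")
        if not 0.0 <= self.min_spike_angle <= 180.0:
            raise ValueError("min_spike_angle must be in [0, 180]")


def read_fixes(path: str | Path) -> list[Fix]:
    """Read a fix CSV, sorted by (animal_id, timestamp).

    Duplicate timestamps within an animal collapse to the fix with the
    better location class.  Malformed rows raise :class:`FixParseError`
    naming the row number.
    """
    path = Path(path)
    fixes: list[Fix] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FixParseError(f"{path}: empty file, no header")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FixParseError(f"{path}: missing column(s) {', '.join(missing)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                fixes.append(
                    Fix(
                        animal_id=row["animal_id"].strip(),
                        timestamp=datetime.fromisoformat(row["timestamp"].strip()),
                        point=GeoPoint(float(row["lon"]), float(row["lat"])),
                        loc_class=row["loc_class"].strip().upper(),
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise FixParseError(f"{path}: row {rownum}: {exc}") from exc
    fixes.sort(key=lambda f: (f.animal_id, f.timestamp, _CLASS_RANK[f.loc_class]))
    deduped: list[Fix] = []
    for f in fixes:
        if deduped and deduped[-1].animal_id == f.animal_id and deduped[-1].timestamp == f.timestamp:
            continue  # keep the better class (sorted first)
        deduped.append(f)
    return deduped


def write_fixes(fixes: Iterable[Fix], path: str | Path) -> None:
    """Write fixes to CSV in the same dialect ``read_fixes`` consumes."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(REQUIRED_COLUMNS)
        for f in fixes:
            w.writerow(
                [
                    f.animal_id,
                    f.timestamp.isoformat(),
                    f"{f.point.lon:.6f}",
                    f"{f.point.lat:.6f}",
                    f.loc_class,
                ]
            )


def read_filter_config(path: str | Path) -> FilterConfig:
    """Parse a ``key=value`` config file into a FilterConfig."""
    kwargs: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key == "keep_classes_always":
            kwargs[key] = frozenset(v.strip().upper() for v in value.split(",") if v.strip())
        elif key in ("max_speed", "min_spike_angle", "max_step"):
            kwargs[key] = float(value)
        else:
            raise ValueError(f"unknown filter config key {key!r}")
    return FilterConfig(**kwargs)


def plausibility_filter(fixes: Sequence[Fix], cfg: FilterConfig | None = None) -> list[Fix]:
    """Screen a single animal's sorted fixes for implausible Doppler jumps.

    A fix is removed when (a) the speed implied from the previously retained
    fix exceeds ``cfg.max_speed``, or (b) it forms a spike: internal turning
    angle below ``cfg.min_spike_angle`` with both adjacent steps longer than
    ``cfg.max_step``.  Fixes whose class is in ``keep_classes_always`` and
    the first and last fixes are always retained.  The retained list is a
    subsequence of the input, and the filter is idempotent.
    """
    cfg = cfg or FilterConfig()
    fixes = list(fixes)
    if len({f.animal_id for f in fixes}) > 1:
        raise ValueError("plausibility_filter expects fixes for a single animal")
    for a, b in zip(fixes, fixes[1:]):
        if b.timestamp < a.timestamp:
            raise ValueError("fixes must be sorted by timestamp")
    if len(fixes) <= 2:
        return fixes

    retained = fixes
    # Re-run until stable: removing a spike can expose a new neighbour pair.
    while True:
        kept = _filter_pass(retained, cfg)
        if len(kept) == len(retained):
            return kept
        retained = kept


def _filter_pass(fixes: list[Fix], cfg: FilterConfig) -> list[Fix]:
    n = len(fixes)
    keep = [True] * n
    last_kept = 0
    for i in range(1, n):
        f = fixes[i]
        exempt = i == n - 1 or f.loc_class in cfg.keep_classes_always
        prev = fixes[last_kept]
        dt_h = (f.timestamp - prev.timestamp).total_seconds() / 3600.0
        step_km = gc_distance(prev.point, f.point)
        if not exempt and dt_h > 0 and step_km / dt_h > cfg.max_speed:
            keep[i] = False
            continue
        if not exempt and i < n - 1:
            nxt = fixes[i + 1]
            ang = turning_angle(prev.point, f.point, nxt.point)
            step_out = gc_distance(f.point, nxt.point)
            if ang < cfg.min_spike_angle and step_km > cfg.max_step and step_out > cfg.max_step:
                keep[i] = False
                continue
        last_kept = i
    return [f for f, k in zip(fixes, keep) if k]
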