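"""Domain types and readers/writers for GPS tracks, camp geometry and person metadata.

The atomic unit of analysis throughout the package is the *person-day*: one
individual's ordered GPS fixes for one local calendar day.  Local dates are
derived at a configurable UTC offset (default +3, East Africa Time).  Field
recordings that run past local midnight are split at midnight into separate
person-day tracks, flagged ``midnight_split``.

Interchange formats are deliberately plain: GPX 1.1 for tracks, RFC 4180 CSV
for tabular tracks and person metadata, GeoJSON (RFC 7946) for camp boundary
polygons.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree
from shapely.geometry import Point, Polygon, shape

#: Local timezone offset used to assign fixes to calendar days (hours).
DEFAULT_UTC_OFFSET_HOURS = 3.0

GPX_NS = "http://www.topografix.com/GPX/1/1"


class TrackParseError(ValueError):
    """Raised when a track file violates the format contract."""


@dataclass(frozen=True)
class TrackPoint:
    """A single timestamped geographic fix (WGS84 degrees, UTC time)."""

    timestamp: datetime
    lon: float
    lat: float
    elevation: float | None = None

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range: {self.lon}")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")
        if self.timestamp.tzinfo is None:
            object.__setattr__(self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc))
        else:
            object.__setattr__(self, "timestamp", self.timestamp.astimezone(timezone.utc))


@dataclass
class Track:
    """One person-day of ordered GPS fixes.

    Invariant: timestamps strictly increasing (duplicate-timestamp fixes are
    collapsed to the first occurrence on read).
    """

    person_id: str
    camp_id: str
    date: date
    points: list[TrackPoint]
    sampling_mode: str = "fixed"  # {"fixed", "adaptive"}
    midnight_split: bool = False

    def __post_init__(self) -> None:
        ts = [p.timestamp for p in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("track timestamps must be strictly increasing")

    @property
    def duration_hours(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return (self.points[-1].timestamp - self.points[0].timestamp).total_seconds() / 3600.0

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class PersonMeta:
    person_id: str
    gender: str  # {"male", "female"}
    age: float
    has_dependent_infant: bool
    camp_id: str

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if not (0.0 <= self.age <= 120.0):
            raise ValueError(f"age out of range: {self.age}")
        if self.has_dependent_infant and self.gender == "male":
            warnings.warn(
                f"person {self.person_id}: dependent-infant flag set for a male; "
                "the flag is only meaningful for females",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GridSpec:
    """Square raster grid in the camp-centred planar frame.

    Cell ``(i, j)`` covers the half-open square
    ``[origin_x + i*s, origin_x + (i+1)*s) x [origin_y + j*s, origin_y + (j+1)*s)``
    with ``s = cell_size`` metres.  ``area_m2`` is the per-cell area A.
    """

    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def area_m2(self) -> float:
        return self.cell_size * self.cell_size


@dataclass
class CampContext:
    """Camp boundary polygon (lon/lat), its centroid and the analysis grid."""

    camp_id: str
    year: int
    boundary: Polygon
    centroid: tuple[float, float] = None  # type: ignore[assignment]
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.is_empty:
            raise ValueError("camp boundary must be a simple non-empty polygon")
        if self.boundary.area == 0:
            raise ValueError("camp boundary polygon is degenerate")
        if self.centroid is None:
            c = self.boundary.centroid
            self.centroid = (c.x, c.y)
        if not self.boundary.covers(Point(*self.centroid)):
            raise ValueError("camp centroid must lie inside the boundary polygon")


# ---------------------------------------------------------------------------
# helpers


def local_date(ts: datetime, utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS) -> date:
    """Calendar day of a UTC instant at the local UTC offset."""
    tz = timezone(timedelta(hours=utc_offset_hours))
    return ts.astimezone(tz).date()


def _dedupe_sorted(points: list[TrackPoint]) -> list[TrackPoint]:
    out: list[TrackPoint] = []
    for p in points:
        if out and p.timestamp == out[-1].timestamp:
            continue  # keep first occurrence
        out.append(p)
    return out


def _split_person_days(
    person_id: str,
    camp_id: str,
    points: list[TrackPoint],
    sampling_mode: str,
    utc_offset_hours: float,
) -> list[Track]:
    """Group a chronological fix sequence into per-local-day Tracks."""
    points = _dedupe_sorted(sorted(points, key=lambda p: p.timestamp))
    tracks: list[Track] = []
    bucket: list[TrackPoint] = []
    cur: date | None = None
    n_days = 0
    for p in points:
        d = local_date(p.timestamp, utc_offset_hours)
        if cur is not None and d != cur:
            tracks.append(
                Track(person_id, camp_id, cur, bucket, sampling_mode, midnight_split=n_days > 0)
            )
            n_days += 1
            bucket = []
        cur = d
        bucket.append(p)
    if bucket:
        tracks.append(
            Track(person_id, camp_id, cur, bucket, sampling_mode, midnight_split=n_days > 0)
        )
    return tracks


# ---------------------------------------------------------------------------
# GPX


def _parse_gpx_time(el: etree._Element, idx: int) -> datetime:
    t = el.findtext(f"{{{GPX_NS}}}time")
    if t is None:
        raise TrackParseError(f"GPX track point #{idx} has no <time> element")
    return datetime.fromisoformat(t.replace("Z", "+00:00"))


def read_gpx(
    path: str | Path, utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS
) -> list[Track]:
    """Read a GPX 1.1 file into person-day Tracks.

    Convention: ``<trk><name>`` carries the person id and ``<trk><cmt>`` the
    camp id (both fall back to the file stem / "unknown").  Each track's fixes
    are sorted by time, duplicate timestamps collapsed to the first, and the
    sequence split into person-days at local midnight.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    tracks: list[Track] = []
    for trk in root.findall(f"{{{GPX_NS}}}trk"):
        person_id = trk.findtext(f"{{{GPX_NS}}}name") or path.stem
        camp_id = trk.findtext(f"{{{GPX_NS}}}cmt") or "unknown"
        points: list[TrackPoint] = []
        idx = 0
        for seg in trk.findall(f"{{{GPX_NS}}}trkseg"):
            for pt in seg.findall(f"{{{GPX_NS}}}trkpt"):
                ts = _parse_gpx_time(pt, idx)
                ele_txt = pt.findtext(f"{{{GPX_NS}}}ele")
                points.append(
                    TrackPoint(
                        timestamp=ts,
                        lon=float(pt.get("lon")),
                        lat=float(pt.get("lat")),
                        elevation=float(ele_txt) if ele_txt is not None else None,
                    )
                )
                idx += 1
        tracks.extend(_split_person_days(person_id, camp_id, points, "fixed", utc_offset_hours))
    return tracks


def write_gpx(tracks: Sequence[Track], path: str | Path) -> None:
    """Write Tracks as GPX 1.1, one <trk> per person-day."""
    root = etree.Element(f"{{{GPX_NS}}}gpx", version="1.1", creator="foragerpath")
    for tr in tracks:
        trk = etree.SubElement(root, f"{{{GPX_NS}}}trk")
        etree.SubElement(trk, f"{{{GPX_NS}}}name").text = tr.person_id
        etree.SubElement(trk, f"{{{GPX_NS}}}cmt").text = tr.camp_id
        seg = etree.SubElement(trk, f"{{{GPX_NS}}}trkseg")
        for p in tr.points:
            pt = etree.SubElement(
                seg, f"{{{GPX_NS}}}trkpt", lat=f"{p.lat:.7f}", lon=f"{p.lon:.7f}"
            )
            if p.elevation is not None:
                etree.SubElement(pt, f"{{{GPX_NS}}}ele").text = f"{p.elevation:.2f}"
            etree.SubElement(pt, f"{{{GPX_NS}}}time").text = (
                p.timestamp.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
            )
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# tracks CSV


def read_tracks_csv(
    path: str | Path,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
    max_bad_fraction: float = 0.01,
) -> tuple[list[Track], list[tuple[int, str]]]:
    """Read a tracks CSV (``person_id,camp_id,timestamp,lon,lat[,ele]``).

    Rows are grouped by (person_id, local calendar day).  Malformed rows are
    collected as ``(line_number, reason)``; if more than ``max_bad_fraction``
    of rows are bad the whole file is rejected.

    Returns ``(tracks, rejected_rows)``.
    """
    path = Path(path)
    by_person: dict[tuple[str, str], list[TrackPoint]] = {}
    rejected: list[tuple[int, str]] = []
    n_rows = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"person_id", "camp_id", "timestamp", "lon", "lat"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TrackParseError(f"missing required columns {sorted(required)} in {path}")
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                ts = datetime.fromisoformat(row["timestamp"].replace("Z", "+00:00"))
                ele = row.get("ele")
                pt = TrackPoint(
                    timestamp=ts,
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    elevation=float(ele) if ele not in (None, "") else None,
                )
            except (ValueError, KeyError) as exc:
                rejected.append((lineno, str(exc)))
                continue
            by_person.setdefault((row["person_id"], row["camp_id"]), []).append(pt)
    if n_rows and len(rejected) / n_rows > max_bad_fraction:
        raise TrackParseError(
            f"{len(rejected)}/{n_rows} rows malformed (> {max_bad_fraction:.0%}); "
            f"first offenders: {rejected[:3]}"
        )
    tracks: list[Track] = []
    for (pid, cid), pts in sorted(by_person.items()):
        tracks.extend(_split_person_days(pid, cid, pts, "fixed", utc_offset_hours))
    return tracks, rejected


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "camp_id", "timestamp", "lon", "lat", "ele"])
        for tr in tracks:
            for p in tr.points:
                writer.writerow(
                    [
                        tr.person_id,
                        tr.camp_id,
                        p.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
                        f"{p.lon:.7f}",
                        f"{p.lat:.7f}",
                        "" if p.elevation is None else f"{p.elevation:.2f}",
                    ]
                )


# ---------------------------------------------------------------------------
# camp GeoJSON


def read_camp_geojson(path: str | Path, cell_size: float = 10.0) -> CampContext:
    """Read a camp boundary from a GeoJSON Polygon feature.

    Feature properties must carry ``camp_id`` and ``year``.  The grid origin
    is anchored at the camp centroid, i.e. (0, 0) in the local planar frame.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        feats = gj["features"]
        if not feats:
            raise TrackParseError("empty FeatureCollection")
        feat = feats[0]
    elif gj.get("type") == "Feature":
        feat = gj
    else:
        raise TrackParseError(f"expected a GeoJSON Feature, got {gj.get('type')!r}")
    geom = shape(feat["geometry"])
    if geom.geom_type != "Polygon":
        raise TrackParseError(f"expected Polygon geometry, got {geom.geom_type}")
    props = feat.get("properties") or {}
    return CampContext(
        camp_id=str(props.get("camp_id", "unknown")),
        year=int(props.get("year", 0)),
        boundary=geom,
        grid=GridSpec(cell_size=cell_size, origin=(0.0, 0.0)),
    )


def write_camp_geojson(camp: CampContext, path: str | Path) -> None:
    feat = {
        "type": "Feature",
        "properties": {"camp_id": camp.camp_id, "year": camp.year},
        "geometry": camp.boundary.__geo_interface__,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": [feat]}, fh)


# ---------------------------------------------------------------------------
# person metadata CSV


def read_persons_csv(path: str | Path) -> list[PersonMeta]:
    """Read person metadata (``person_id,gender,age,has_dependent_infant,camp_id``)."""
    persons: list[PersonMeta] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            persons.append(
                PersonMeta(
                    person_id=row["person_id"],
                    gender=row["gender"],
                    age=float(row["age"]),
                    has_dependent_infant=row["has_dependent_infant"].strip().lower()
                    in ("1", "true", "yes"),
                    camp_id=row["camp_id"],
                )
            )
    return persons


def write_persons_csv(persons: Iterable[PersonMeta], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "gender", "age", "has_dependent_infant", "camp_id"])
        for p in persons:
            writer.writerow(
                [p.person_id, p.gender, p.age, str(p.has_dependent_infant).lower(), p.camp_id]
            )
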