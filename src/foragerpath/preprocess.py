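"""Track cleaning, projection, resampling and bout extraction.

Processing order for a raw person-day track:

1. :func:`project_to_local` — camp-centred equirectangular projection.
2. :func:`resample_5s` — linear interpolation onto an even 5 s grid.
3. :func:`filter_vehicle_day` — drop whole days with sustained vehicle-speed
   travel (run before spike filtering so the evidence cannot be erased).
4. :func:`filter_speed` — iterative removal of spatially errant fixes by a
   hard speed ceiling, then by a multiple of the modal moving speed.
5. :func:`classify_in_camp` — label each fix in/out of the camp polygon.

Day-level quantities (:func:`daily_distance`, inclusion by recorded span) and
the principal out-of-camp excursion (:func:`extract_primary_bout`) are
computed from the cleaned, annotated track.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .trackio import CampContext, Track

#: Mean Earth radius (IUGG), metres.
EARTH_RADIUS_M = 6_371_008.8

#: Default fix interval after resampling, seconds.
RESAMPLE_INTERVAL_S = 5.0

#: Gaps longer than this are bridged by interpolation but flagged, seconds.
GAP_FLAG_S = 300.0


@dataclass
class ProjectedTrack:
    """A track in camp-centred planar coordinates with per-point annotations.

    ``t`` holds seconds since the Unix epoch (UTC).  ``gap_filled`` marks
    points interpolated across recording gaps longer than the flag threshold;
    such spans count toward daily distance but are excluded from shape
    statistics (sinuosity).
    """

    person_id: str
    camp_id: str
    date: object
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    in_camp: np.ndarray | None = None
    gap_filled: np.ndarray | None = None
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.gap_filled is None:
            self.gap_filled = np.zeros(len(self.t), dtype=bool)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dist_from_camp(self) -> np.ndarray:
        """Distance of each fix from the camp centroid (the planar origin), m."""
        return np.hypot(self.x, self.y)

    @property
    def duration_hours(self) -> float:
        return 0.0 if len(self.t) < 2 else (self.t[-1] - self.t[0]) / 3600.0

    def segment_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def path_length(self) -> float:
        return float(self.segment_lengths().sum())

    def segment_speeds(self) -> np.ndarray:
        dt = np.diff(self.t)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(dt > 0, self.segment_lengths() / dt, 0.0)


@dataclass
class Bout:
    """A day's principal out-of-camp excursion, split at its apex.

    The apex is the point of maximum distance from the camp centroid (ties
    broken to the earliest such point).  Index ranges are inclusive and refer
    to the parent :class:`ProjectedTrack`; endpoints are the last in-camp fix
    before departure and the first in-camp fix after return, so the outbound
    and inbound chords are camp-anchored.
    """

    start: int
    apex_index: int
    end: int
    outbound_path_length: float
    inbound_path_length: float
    outbound_chord: float
    inbound_chord: float
    max_dist_from_camp: float
    gap_fraction: float = 0.0


# ---------------------------------------------------------------------------
# projection


def project_to_local(track: Track, camp: CampContext) -> ProjectedTrack:
    """Project WGS84 fixes into a camp-centred equirectangular planar frame.

    x = R * dlon * cos(lat0), y = R * dlat (radians), with the camp centroid
    at the origin.  Valid for tracks within 200 km of the centroid, where the
    planar distance error relative to the sphere is below 0.1%.
    """
    lon0, lat0 = camp.centroid
    lat0_r = math.radians(lat0)
    lon = np.array([p.lon for p in track.points], dtype=float)
    lat = np.array([p.lat for p in track.points], dtype=float)
    x = EARTH_RADIUS_M * np.radians(lon - lon0) * math.cos(lat0_r)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    r = np.hypot(x, y)
    if r.size and r.max() > 200_000.0:
        raise ValueError(
            f"track {track.person_id}/{track.date}: fix {int(r.argmax())} is "
            f"{r.max() / 1000:.0f} km from camp; beyond projection validity (200 km)"
        )
    t = np.array([p.timestamp.timestamp() for p in track.points], dtype=float)
    return ProjectedTrack(track.person_id, track.camp_id, track.date, t, x, y)


def project_polygon(poly: Polygon, camp: CampContext) -> Polygon:
    """Project a lon/lat polygon into the same camp-centred planar frame."""
    lon0, lat0 = camp.centroid
    cos0 = math.cos(math.radians(lat0))
    ext = np.asarray(poly.exterior.coords)
    x = EARTH_RADIUS_M * np.radians(ext[:, 0] - lon0) * cos0
    y = EARTH_RADIUS_M * np.radians(ext[:, 1] - lat0)
    return Polygon(np.column_stack([x, y]))


def haversine_m(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance on the sphere, metres (reference for the projection)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


# ---------------------------------------------------------------------------
# resampling


def resample_5s(
    ptrack: ProjectedTrack,
    interval: float = RESAMPLE_INTERVAL_S,
    gap_flag_s: float = GAP_FLAG_S,
) -> ProjectedTrack:
    """Linearly interpolate fixes onto the even grid t0, t0+interval, ... <= t_end.

    No extrapolation beyond the recorded span.  Spans bridged across source
    gaps longer than ``gap_flag_s`` are flagged ``gap_filled``.  A track
    already on the exact grid is returned unchanged (idempotence).
    """
    if len(ptrack) < 2:
        return ptrack
    t0, t_end = ptrack.t[0], ptrack.t[-1]
    n = int(math.floor((t_end - t0) / interval)) + 1
    tg = t0 + interval * np.arange(n)
    x = np.interp(tg, ptrack.t, ptrack.x)
    y = np.interp(tg, ptrack.t, ptrack.y)
    # a grid point is gap-filled if it falls strictly inside a long source gap
    gaps = np.diff(ptrack.t)
    flagged = np.zeros(n, dtype=bool)
    for k in np.nonzero(gaps > gap_flag_s)[0]:
        flagged |= (tg > ptrack.t[k]) & (tg < ptrack.t[k + 1])
    out = ProjectedTrack(
        ptrack.person_id, ptrack.camp_id, ptrack.date, tg, x, y, gap_filled=flagged,
        log=list(ptrack.log),
    )
    out.log.append({"op": "resample", "interval_s": interval, "n_in": len(ptrack), "n_out": n})
    return out


# ---------------------------------------------------------------------------
# speed filters


def _both_neighbour_violations(p: ProjectedTrack, limit: float) -> np.ndarray:
    """Mask of points whose implied speed to *every* neighbour exceeds ``limit``.

    Endpoints have a single neighbour and are judged on that one speed.
    """
    v = p.segment_speeds()
    n = len(p)
    bad = np.zeros(n, dtype=bool)
    if n < 2:
        return bad
    bad[0] = v[0] > limit
    bad[-1] = v[-1] > limit
    if n > 2:
        bad[1:-1] = (v[:-1] > limit) & (v[1:] > limit)
    return bad


def _drop(p: ProjectedTrack, keep: np.ndarray) -> ProjectedTrack:
    return ProjectedTrack(
        p.person_id, p.camp_id, p.date, p.t[keep], p.x[keep], p.y[keep],
        in_camp=None if p.in_camp is None else p.in_camp[keep],
        gap_filled=p.gap_filled[keep], log=list(p.log),
    )


def filter_speed(
    ptrack: ProjectedTrack,
    max_speed: float = 20.0 / 3.6,
    modal_multiplier: float = 10.0,
    modal_bin: float = 0.1,
    min_moving_speed: float = 0.5,
) -> ProjectedTrack:
    """Remove spatially errant fixes by maximum and modal movement speed.

    Stage 1 iteratively removes any fix whose implied speeds from both
    neighbours exceed ``max_speed`` (default 20 km/h, a pedestrian ceiling)
    until a fixed point is reached.  Stage 2 applies the same rule with the
    limit ``modal_multiplier`` times the modal moving speed (mode of
    ``modal_bin``-wide speed bins over segments faster than
    ``min_moving_speed``; days with long stationary periods would otherwise
    have a near-zero mode).  Removal counts are logged; >10% removed raises a
    warning, >50% an error.
    """
    if len(ptrack) < 3:
        return ptrack
    p = ptrack
    n0 = len(p)
    removed = 0
    while True:
        bad = _both_neighbour_violations(p, max_speed)
        if not bad.any():
            break
        removed += int(bad.sum())
        p = _drop(p, ~bad)
        if len(p) < 3:
            break
    # modal stage
    v = p.segment_speeds()
    moving = v[v >= min_moving_speed]
    if moving.size:
        counts = np.bincount((moving / modal_bin).astype(int))
        modal_speed = (np.argmax(counts) + 0.5) * modal_bin
        limit = modal_multiplier * modal_speed
        while True:
            bad = _both_neighbour_violations(p, limit)
            if not bad.any():
                break
            removed += int(bad.sum())
            p = _drop(p, ~bad)
            if len(p) < 3:
                break
    frac = removed / n0 if n0 else 0.0
    p.log.append({"op": "filter_speed", "removed": removed, "fraction": frac})
    if frac > 0.5:
        raise ValueError(
            f"track {p.person_id}/{p.date}: speed filter removed {frac:.0%} of fixes; unusable"
        )
    if frac > 0.1:
        warnings.warn(
            f"track {p.person_id}/{p.date}: speed filter removed {frac:.0%} of fixes",
            stacklevel=2,
        )
    return p


def filter_vehicle_day(
    ptrack: ProjectedTrack,
    vehicle_speed_threshold: float = 3.5,
    min_duration: float = 120.0,
) -> tuple[bool, dict]:
    """Decide whether a person-day is pedestrian travel.

    Returns ``(keep, evidence)``.  The day is dropped when implied speed
    stays above ``vehicle_speed_threshold`` (m/s) for a contiguous run longer
    than ``min_duration`` seconds — the signature of a motorcycle/bicycle
    ride, which single errant fixes cannot mimic.
    """
    v = ptrack.segment_speeds()
    dt = np.diff(ptrack.t)
    fast = v > vehicle_speed_threshold
    longest = 0.0
    run = 0.0
    for f, d in zip(fast, dt):
        run = run + d if f else 0.0
        longest = max(longest, run)
    keep = longest <= min_duration
    evidence = {
        "op": "vehicle_filter",
        "longest_fast_run_s": longest,
        "threshold_mps": vehicle_speed_threshold,
        "min_duration_s": min_duration,
        "keep": keep,
    }
    ptrack.log.append(evidence)
    return keep, evidence


# ---------------------------------------------------------------------------
# in/out of camp, inclusion, distance


def classify_in_camp(ptrack: ProjectedTrack, camp: CampContext) -> ProjectedTrack:
    """Label each fix in/out of camp by point-in-polygon (boundary counts as in)."""
    poly = project_polygon(camp.boundary, camp)
    inside = shapely.intersects_xy(poly, ptrack.x, ptrack.y)
    ptrack.in_camp = np.asarray(inside, dtype=bool)
    return ptrack


def apply_inclusion(
    ptracks: Sequence[ProjectedTrack], min_hours: float = 8.0
) -> tuple[list[ProjectedTrack], int]:
    """Keep tracks whose recorded span is at least ``min_hours``.

    Returns ``(kept, n_excluded)``.  The rule uses the recorded span
    (t_end - t0), not the fix count.
    """
    kept = [p for p in ptracks if p.duration_hours >= min_hours]
    return kept, len(ptracks) - len(kept)


def daily_distance(ptrack: ProjectedTrack) -> float:
    """Total distance travelled over the day in km (all travel, in and out of camp)."""
    if len(ptrack) < 2:
        warnings.warn(f"track {ptrack.person_id}/{ptrack.date}: fewer than 2 fixes", stacklevel=2)
        return 0.0
    return ptrack.path_length() / 1000.0


# ---------------------------------------------------------------------------
# bout extraction


def extract_primary_bout(ptrack: ProjectedTrack, min_range: float = 500.0) -> Bout | None:
    """Extract the day's principal out-of-camp excursion.

    Bouts are maximal runs of out-of-camp fixes, bracketed by the last
    in-camp fix before departure and the first in-camp fix after return.
    Bouts never reaching ``min_range`` metres from the camp centroid are
    discarded; among the rest the one with the greatest total path length is
    selected and split at its apex (earliest point of maximum distance).
    """
    if ptrack.in_camp is None:
        raise ValueError("classify_in_camp must run before bout extraction")
    inc = ptrack.in_camp
    n = len(ptrack)
    dist = ptrack.dist_from_camp
    seg = ptrack.segment_lengths()
    bouts: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not inc[i]:
            j = i
            while j < n and not inc[j]:
                j += 1
            start = i - 1 if i > 0 else i  # last in-camp fix before departure
            end = j if j < n else j - 1    # first in-camp fix after return
            bouts.append((start, end))
            i = j
        else:
            i += 1
    best: tuple[float, int, int] | None = None
    for start, end in bouts:
        if dist[start:end + 1].max() < min_range:
            continue
        length = float(seg[start:end].sum())
        if best is None or length > best[0]:
            best = (length, start, end)
    if best is None:
        return None
    _, start, end = best
    apex = start + int(np.argmax(dist[start:end + 1]))  # argmax -> earliest tie
    out_len = float(seg[start:apex].sum())
    in_len = float(seg[apex:end].sum())
    out_chord = float(np.hypot(ptrack.x[apex] - ptrack.x[start], ptrack.y[apex] - ptrack.y[start]))
    in_chord = float(np.hypot(ptrack.x[end] - ptrack.x[apex], ptrack.y[end] - ptrack.y[apex]))
    gap_frac = float(ptrack.gap_filled[start:end + 1].mean())
    return Bout(
        start=start,
        apex_index=apex,
        end=end,
        outbound_path_length=out_len,
        inbound_path_length=in_len,
        outbound_chord=out_chord,
        inbound_chord=in_chord,
        max_dist_from_camp=float(dist[start:end + 1].max()),
        gap_fraction=gap_frac,
    )
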