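"""Synthetic central-place-forager GPS tracks.

Every downstream stage of the pipeline is exercised on simulated data,
because real foraging GPS corpora of this kind are privacy-restricted.  The
generator is a biased von Mises random walk anchored to a camp:

* a person-day spans ~11.5 h of recording at a 5 s fix interval;
* the day contains one out-of-camp foray: an outbound walk whose headings
  are von Mises-distributed around the bearing to a drawn apex point
  (concentration kappa — low kappa = tortuous search, high kappa = direct
  travel), a foraging dwell at the apex, and an inbound walk biased toward
  camp;
* in camp, people sit at hearth spots and occasionally hop between them;
* GPS error is AR(1)-correlated (a smoothed receiver drifts slowly; its
  error is not white at 5 s), plus rare errant fixes and optional
  vehicle-speed contamination to exercise the cleaning stages.

Gendered movement structure is controlled through
:class:`ForagerProfile`: day range (men ~14 km vs women ~8 km for adults),
heading concentration (men lower — more sinuous search), and foraging party
structure (women in cohesive metre-spaced parties, men solitary).  The mean
day range is calibrated so the *noiseless* planned path of an average day
(in-camp hops + foray + dwell) has that total length; the manifest records
each day's realized noiseless path as ground truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from datetime import date as date_t, datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import i0, i1
from shapely.geometry import Point, Polygon

from .preprocess import EARTH_RADIUS_M
from .trackio import (
    CampContext,
    GridSpec,
    PersonMeta,
    Track,
    TrackPoint,
    write_camp_geojson,
    write_gpx,
    write_persons_csv,
)

EAT = timezone(timedelta(hours=3))


@dataclass(frozen=True)
class ForagerProfile:
    """Movement parameters for one forager class.

    ``mean_day_range`` is the expected total noiseless path per day (km);
    ``turning_concentration`` is the von Mises kappa of step headings around
    the bearing to the current goal; ``foray_target_distance`` (km) is the
    mean apex distance from camp — when None it is calibrated from the day
    range; ``party_spacing`` (m) is the stationary SD of each member's
    smooth spatial offset from the party's shared path.
    """

    gender: str
    mean_day_range: float = 10.0          # km/day
    turning_concentration: float = 8.0    # kappa >= 0
    foray_target_distance: float | None = None  # km
    party_size: int = 1
    party_spacing: float = 0.0            # metres
    out_time: float | None = None         # hours/day, derived if None
    speed: float = 1.25                   # m/s walking pace

    def __post_init__(self) -> None:
        if self.mean_day_range <= 0 or self.speed <= 0:
            raise ValueError("mean_day_range and speed must be positive")
        if self.turning_concentration < 0 or self.party_size < 1 or self.party_spacing < 0:
            raise ValueError("invalid profile parameters")

    @property
    def straightness(self) -> float:
        """Expected straightness rho(kappa) = I1(kappa)/I0(kappa) of a leg."""
        k = self.turning_concentration
        if k > 700:  # I0 overflows; limit is 1
            return 1.0
        return float(i1(k) / i0(k))


#: Default adult profiles: men range ~14 km/day on tortuous solitary hunts,
#: women ~8 km/day on direct group gathering trips with metres-scale spacing.
MALE_PROFILE = ForagerProfile(
    gender="male", mean_day_range=14.0, turning_concentration=1.7,
    party_size=1, party_spacing=0.0,
)
FEMALE_PROFILE = ForagerProfile(
    gender="female", mean_day_range=8.0, turning_concentration=2.2,
    party_size=4, party_spacing=3.0,
)


@dataclass
class SimConfig:
    """Full synthetic-camp configuration (deterministic given ``seed``)."""

    camp: CampContext | None = None
    camp_radius_m: float = 150.0
    profiles: tuple[ForagerProfile, ...] = (MALE_PROFILE, FEMALE_PROFILE)
    n_persons: int = 10                    # per profile
    n_days: int = 5
    sample_interval: float = 5.0           # seconds
    adaptive: bool = False                 # emulate adaptive logging
    fix_noise_sd: float = 1.5              # metres (AR(1) stationary SD)
    fix_noise_tau: float = 600.0           # seconds (AR(1) correlation time)
    errant_fix_rate: float = 2e-4          # per fix
    vehicle_segment: tuple[float, float] | None = None  # (speed m/s, duration s)
    day_span_mean_h: float = 11.5
    day_span_sd_h: float = 1.0
    dwell_min_s: float = 1200.0            # foraging dwell at the apex
    dwell_max_s: float = 2400.0
    landscape_bound_m: float = 20_000.0
    start_date: date_t = date_t(2018, 7, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.sample_interval <= 0:
            raise ValueError("n_days >= 1 and sample_interval > 0 required")
        if self.camp is None:
            self.camp = make_circular_camp(radius_m=self.camp_radius_m)


@dataclass
class SimResult:
    tracks: list[Track]
    persons: list[PersonMeta]
    camp: CampContext
    manifest: pd.DataFrame


# ---------------------------------------------------------------------------
# camp construction and coordinate helpers

DEFAULT_CAMP_LON = 35.0
DEFAULT_CAMP_LAT = -3.6


def make_circular_camp(
    lon: float = DEFAULT_CAMP_LON,
    lat: float = DEFAULT_CAMP_LAT,
    radius_m: float = 150.0,
    camp_id: str = "simcamp",
    year: int = 2018,
    n_vertices: int = 48,
) -> CampContext:
    """A circular camp boundary of the given radius around (lon, lat)."""
    ang = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    x = radius_m * np.cos(ang)
    y = radius_m * np.sin(ang)
    lons, lats = planar_to_lonlat(x, y, lon, lat)
    return CampContext(
        camp_id=camp_id, year=year, boundary=Polygon(np.column_stack([lons, lats])),
        grid=GridSpec(cell_size=10.0, origin=(0.0, 0.0)),
    )


def planar_to_lonlat(x, y, lon0: float, lat0: float):
    """Inverse of the camp-centred equirectangular projection."""
    lat = lat0 + np.degrees(np.asarray(y) / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(np.asarray(x) / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    return lon, lat


def _subrng(seed: int, *keys: str | int) -> np.random.Generator:
    """Per-(person|party)-day RNG substream via stable hashing of the keys."""
    ints = [seed & 0x7FFFFFFF]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode("utf-8")))
    return np.random.default_rng(ints)


# ---------------------------------------------------------------------------
# planned (noiseless) day construction

_HOP_INTERVAL_S = 1500.0   # mean time between in-camp hearth hops
_HOP_RADIUS_M = 40.0       # hearth spots drawn within this radius of centre
_DWELL_STEP_M = 0.3        # slow foraging shuffle at the apex, per 5 s fix


def _calibrate_chord(profile: ForagerProfile, cfg: SimConfig) -> float:
    """Apex chord distance (m) such that the expected noiseless day path
    equals the profile's mean day range.  Fixed-point on the in-camp
    movement allowance, which depends on time left over from the foray."""
    rho = max(profile.straightness, 1e-3)
    span_s = cfg.day_span_mean_h * 3600.0
    dwell_s = 0.5 * (cfg.dwell_min_s + cfg.dwell_max_s)
    dwell_len = dwell_s / cfg.sample_interval * _DWELL_STEP_M
    hop_rate = (2.0 / 3.0 * _HOP_RADIUS_M) / _HOP_INTERVAL_S  # m/s of hop movement
    budget = profile.mean_day_range * 1000.0
    for _ in range(6):
        t_walk = budget / profile.speed
        t_in_camp = max(span_s - t_walk - dwell_s, 0.0)
        allowance = t_in_camp * hop_rate + dwell_len
        budget = max(profile.mean_day_range * 1000.0 - allowance, 1000.0)
    return rho * budget / 2.0


def _walk_leg(
    start: np.ndarray,
    target: np.ndarray,
    kappa: float,
    step: float,
    rng: np.random.Generator,
    max_steps: int,
) -> np.ndarray:
    """Biased von Mises walk from start until within one step of target."""
    pos = start.astype(float).copy()
    out = []
    for _ in range(max_steps):
        delta = target - pos
        dist = math.hypot(*delta)
        if dist <= step:
            break
        bearing = math.atan2(delta[1], delta[0])
        heading = rng.vonmises(bearing, kappa) if kappa > 0 else rng.uniform(-math.pi, math.pi)
        pos = pos + step * np.array([math.cos(heading), math.sin(heading)])
        out.append(pos.copy())
    out.append(target.astype(float).copy())
    return np.array(out)


def _in_camp_segment(
    start: np.ndarray, duration_s: float, interval: float,
    rng: np.random.Generator, speed: float,
) -> np.ndarray:
    """Piecewise-stationary hearth positions with occasional short hops."""
    n = max(int(round(duration_s / interval)), 0)
    pts = np.empty((n, 2))
    pos = start.astype(float).copy()
    k = 0
    while k < n:
        stay = max(int(rng.exponential(_HOP_INTERVAL_S) / interval), 1)
        stop = min(k + stay, n)
        pts[k:stop] = pos
        k = stop
        if k >= n:
            break
        r = _HOP_RADIUS_M * math.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * math.pi)
        new = np.array([r * math.cos(ang), r * math.sin(ang)])
        n_transit = max(int(math.hypot(*(new - pos)) / (speed * interval)), 1)
        for j in range(n_transit):
            if k >= n:
                break
            pts[k] = pos + (new - pos) * (j + 1) / n_transit
            k += 1
        pos = new
    return pts


def plan_person_day(
    profile: ForagerProfile,
    camp: CampContext,
    rng: np.random.Generator,
    cfg: SimConfig,
) -> tuple[np.ndarray, dict]:
    """Noiseless planned positions at the fix interval, plus ground truth.

    The day: in-camp morning, outbound biased walk to a drawn apex, a
    foraging dwell there, inbound biased walk home, in-camp evening.  The
    track begins and ends inside the camp polygon.
    """
    interval = cfg.sample_interval
    step = profile.speed * interval
    kappa = profile.turning_concentration
    span_s = float(np.clip(rng.normal(cfg.day_span_mean_h, cfg.day_span_sd_h), 8.5, 13.0) * 3600)
    n_total = int(span_s / interval)

    chord_mean = (
        profile.foray_target_distance * 1000.0
        if profile.foray_target_distance is not None
        else _calibrate_chord(profile, cfg)
    )
    for attempt in range(100):
        chord = chord_mean * rng.lognormal(-0.5 * 0.2 ** 2, 0.2)
        if chord < cfg.landscape_bound_m:
            break
    else:
        raise RuntimeError("could not draw an apex inside the landscape bound")
    bearing = rng.uniform(0, 2 * math.pi)
    apex = chord * np.array([math.cos(bearing), math.sin(bearing)])

    start = np.array([0.0, 0.0])
    rho = max(profile.straightness, 1e-3)
    cap = int(3 * chord / (rho * step)) + 10

    morning_s = rng.uniform(0.5, 2.0) * 3600
    morning = _in_camp_segment(start, morning_s, interval, rng, profile.speed)
    depart = morning[-1] if len(morning) else start

    outbound = _walk_leg(depart, apex, kappa, step, rng, cap)

    dwell_s = rng.uniform(cfg.dwell_min_s, cfg.dwell_max_s)
    n_dwell = int(dwell_s / interval)
    shuffle = np.cumsum(rng.normal(0, _DWELL_STEP_M / math.sqrt(2), (n_dwell, 2)), axis=0)
    if n_dwell:
        # Brownian bridge back to the apex so the inbound leg starts there
        shuffle -= (np.arange(1, n_dwell + 1) / n_dwell)[:, None] * shuffle[-1]
    dwell = apex + shuffle

    inbound = _walk_leg(apex if n_dwell == 0 else dwell[-1], start, kappa, step, rng, cap)

    parts = [p for p in (morning, outbound, dwell, inbound) if len(p)]
    path = np.vstack(parts)
    if len(path) < n_total:
        evening = _in_camp_segment(path[-1], (n_total - len(path)) * interval,
                                   interval, rng, profile.speed)
        if len(evening):
            path = np.vstack([path, evening])
    seg = np.hypot(*np.diff(path, axis=0).T)
    truth = {
        "true_day_range_km": float(seg.sum()) / 1000.0,
        "apex_x": float(apex[0]),
        "apex_y": float(apex[1]),
        "apex_dist_m": float(chord),
        "span_h": span_s / 3600.0,
    }
    return path, truth


# ---------------------------------------------------------------------------
# noise, contamination, track assembly


def _ar1_noise(n: int, sd: float, tau: float, interval: float,
               rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros((n, 2))
    phi = math.exp(-interval / tau)
    innov_sd = sd * math.sqrt(1 - phi * phi)
    eps = rng.normal(0, innov_sd, (n, 2))
    eps[0] = rng.normal(0, sd, 2)  # stationary start
    return lfilter([1.0], [1.0, -phi], eps, axis=0)


def _party_offset(n: int, sd: float, rng: np.random.Generator,
                  knot_steps: int = 360) -> np.ndarray:
    """Smooth spatial offset of a party member from the shared path.

    Gaussian offsets with stationary SD ``sd`` are drawn at ~30 min knots
    and linearly interpolated, so a member holds a near-constant position in
    the walking line; the offset contributes essentially no extra path
    length, unlike fix-rate jitter would.
    """
    if sd == 0 or n == 0:
        return np.zeros((n, 2))
    n_knots = max(n // knot_steps, 1) + 1
    knots_t = np.linspace(0, n - 1, n_knots)
    knots = rng.normal(0, sd, (n_knots, 2))
    t = np.arange(n)
    return np.column_stack([np.interp(t, knots_t, knots[:, k]) for k in (0, 1)])


def _apply_contamination(
    path: np.ndarray, interval: float, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Errant fixes and optional vehicle-speed segment."""
    n = len(path)
    path = path.copy()
    if cfg.vehicle_segment is not None:
        v_speed, v_dur = cfg.vehicle_segment
        n_seg = int(v_dur / interval)
        if 0 < n_seg < n - 4:
            k0 = int(rng.integers(2, n - n_seg - 2))
            ang = rng.uniform(0, 2 * math.pi)
            direction = np.array([math.cos(ang), math.sin(ang)])
            ride = path[k0] + np.outer(np.arange(1, n_seg + 1) * v_speed * interval, direction)
            shift = ride[-1] - path[k0 + n_seg]
            path[k0 + 1:k0 + n_seg + 1] = ride
            path[k0 + n_seg + 1:] += shift  # remainder of the day continues from the drop-off
    if cfg.errant_fix_rate > 0 and n > 4:
        errant = rng.uniform(size=n) < cfg.errant_fix_rate
        errant[:2] = errant[-2:] = False  # track must begin/end in camp
        for k in np.nonzero(errant)[0]:
            r = 5000.0 * math.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * math.pi)
            path[k] = [r * math.cos(ang), r * math.sin(ang)]
    return path


def _thin_adaptive(t: np.ndarray, xy: np.ndarray, interval: float) -> np.ndarray:
    """Adaptive-logging emulation: one fix per 15 s while nearly stationary.

    Mirrors devices that record densely while the wearer moves and sparsely
    while they rest (speed < 0.2 m/s).
    """
    n = len(t)
    keep = np.ones(n, dtype=bool)
    speeds = np.hypot(*np.diff(xy, axis=0).T) / np.diff(t)
    last_kept = t[0]
    for k in range(1, n - 1):
        slow = speeds[k - 1] < 0.2 and speeds[k] < 0.2
        if slow and (t[k] - last_kept) < 15.0 - 1e-9:
            keep[k] = False
        else:
            last_kept = t[k]
    return keep


def _assemble_track(
    person_id: str,
    camp: CampContext,
    day: date_t,
    path: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    start_min: float = 0.0,
) -> Track:
    interval = cfg.sample_interval
    n = len(path)
    noisy = path + _ar1_noise(n, cfg.fix_noise_sd, cfg.fix_noise_tau, interval, rng)
    noisy = _apply_contamination(noisy, interval, cfg, rng)
    t0 = datetime.combine(day, datetime.min.time(), tzinfo=EAT) + timedelta(
        hours=7, minutes=45 + start_min
    )
    t0 = t0.replace(microsecond=0)
    t = np.arange(n) * interval
    if cfg.adaptive:
        keep = _thin_adaptive(t, noisy, interval)
        t, noisy = t[keep], noisy[keep]
    lon0, lat0 = camp.centroid
    lons, lats = planar_to_lonlat(noisy[:, 0], noisy[:, 1], lon0, lat0)
    points = [
        TrackPoint(timestamp=t0 + timedelta(seconds=float(dt)), lon=lo, lat=la)
        for dt, lo, la in zip(t, lons, lats)
    ]
    return Track(
        person_id=person_id,
        camp_id=camp.camp_id,
        date=day,
        points=points,
        sampling_mode="adaptive" if cfg.adaptive else "fixed",
    )


# ---------------------------------------------------------------------------
# public operations


def simulate_person_day(
    profile: ForagerProfile,
    camp: CampContext,
    rng: np.random.Generator,
    cfg: SimConfig | None = None,
    person_id: str = "p0",
    day: date_t = date_t(2018, 7, 1),
    return_truth: bool = False,
):
    """One synthetic person-day Track (optionally with its ground truth)."""
    cfg = cfg if cfg is not None else SimConfig(camp=camp)
    path, truth = plan_person_day(profile, camp, rng, cfg)
    track = _assemble_track(person_id, camp, day, path, cfg, rng,
                            start_min=rng.uniform(-15, 15))
    return (track, truth) if return_truth else track


def simulate_party(
    profiles: Sequence[ForagerProfile],
    camp: CampContext,
    rng: np.random.Generator,
    cfg: SimConfig | None = None,
    person_ids: Sequence[str] | None = None,
    day: date_t = date_t(2018, 7, 1),
    return_truth: bool = False,
):
    """Tracks for a foraging party sharing one planned path.

    Each member's realized path is the shared plan plus a smooth AR(1)
    spatial offset with stationary SD ``party_spacing`` (correlation time
    120 s), then fix noise; timestamps are aligned across members.
    """
    cfg = cfg if cfg is not None else SimConfig(camp=camp)
    lead = profiles[0]
    if person_ids is None:
        person_ids = [f"p{k}" for k in range(len(profiles))]
    path, truth = plan_person_day(lead, camp, rng, cfg)
    start_min = rng.uniform(-15, 15)  # shared: member timestamps stay aligned
    tracks = []
    truths = []
    for pid, prof in zip(person_ids, profiles):
        member_rng = _subrng(cfg.seed, pid, str(day))
        offset = _party_offset(len(path), prof.party_spacing, member_rng)
        member_path = path + offset
        seg = np.hypot(*np.diff(member_path, axis=0).T)
        tracks.append(_assemble_track(pid, camp, day, member_path, cfg, member_rng,
                                      start_min=start_min))
        truths.append(dict(truth, person_id=pid,
                           true_day_range_km=float(seg.sum()) / 1000.0))
    return (tracks, truths) if return_truth else tracks


def simulate_camp(config: SimConfig) -> SimResult:
    """A full synthetic camp: tracks, person metadata and a ground-truth manifest.

    Persons are assigned to foraging parties profile by profile (party size
    from the profile; men default to solitary, women to parties of four).
    Each party shares one planned path per day, generated from an RNG
    substream keyed by (seed, party id, day) so per-track reproducibility
    survives reordering.
    """
    camp = config.camp
    persons: list[PersonMeta] = []
    parties: list[tuple[str, list[tuple[str, ForagerProfile]]]] = []
    meta_rng = _subrng(config.seed, "persons")
    pid_counter = 0
    for prof in config.profiles:
        ids = []
        for _ in range(config.n_persons):
            pid = f"{prof.gender[0]}{pid_counter:03d}"
            pid_counter += 1
            persons.append(
                PersonMeta(
                    person_id=pid,
                    gender=prof.gender,
                    age=float(meta_rng.integers(18, 61)),
                    has_dependent_infant=(
                        prof.gender == "female" and bool(meta_rng.uniform() < 0.3)
                    ),
                    camp_id=camp.camp_id,
                )
            )
            ids.append(pid)
        for k in range(0, len(ids), prof.party_size):
            members = [(pid, prof) for pid in ids[k:k + prof.party_size]]
            parties.append((f"party_{prof.gender}_{k // prof.party_size}", members))

    tracks: list[Track] = []
    manifest_rows = []
    for d in range(config.n_days):
        day = config.start_date + timedelta(days=d)
        for party_id, members in parties:
            rng = _subrng(config.seed, party_id, str(day))
            ptracks, truths = simulate_party(
                [prof for _, prof in members],
                camp,
                rng,
                cfg=config,
                person_ids=[pid for pid, _ in members],
                day=day,
                return_truth=True,
            )
            tracks.extend(ptracks)
            for tr, truth in zip(ptracks, truths):
                manifest_rows.append(
                    dict(
                        person_id=tr.person_id,
                        date=day.isoformat(),
                        gender=members[0][1].gender,
                        party_id=party_id,
                        party_size=len(members),
                        **{k: v for k, v in truth.items() if k != "person_id"},
                    )
                )
    manifest = pd.DataFrame(manifest_rows)
    return SimResult(tracks=tracks, persons=persons, camp=camp, manifest=manifest)


def write_sim_outputs(result: SimResult, out_dir: str | Path) -> None:
    """Write GPX per person-day, persons.csv, camp.geojson and manifest.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks_dir = out / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for tr in result.tracks:
        write_gpx([tr], tracks_dir / f"{tr.person_id}_{tr.date.isoformat()}.gpx")
    write_persons_csv(result.persons, out / "persons.csv")
    write_camp_geojson(result.camp, out / "camp.geojson")
    result.manifest.to_csv(out / "manifest.csv", index=False)
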