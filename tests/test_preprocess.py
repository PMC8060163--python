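"""Projection, speed filtering, resampling, inclusion and bout extraction."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from conftest import make_ptrack
from foragerpath import preprocess as prep
from foragerpath.trackio import Track, TrackPoint

UTC = timezone.utc
T0 = datetime(2018, 7, 1, 5, 0, tzinfo=UTC)


# ---------------------------------------------------------------------------
# projection


def test_projection_centroid_maps_to_origin(camp):
    lon0, lat0 = camp.centroid
    track = Track("p", "c", T0.date(), [
        TrackPoint(T0, lon0, lat0), TrackPoint(T0 + timedelta(seconds=5), lon0, lat0 + 0.001),
    ])
    p = prep.project_to_local(track, camp)
    assert p.x[0] == pytest.approx(0.0, abs=1e-9)
    assert p.y[0] == pytest.approx(0.0, abs=1e-9)
    # 0.001 degrees of latitude is 111.195 m on the sphere
    assert p.y[1] == pytest.approx(111.195, abs=0.001)


def test_projection_agrees_with_haversine_within_20km(camp):
    lon0, lat0 = camp.centroid
    rng = np.random.default_rng(7)
    for _ in range(200):
        dlon = rng.uniform(-0.09, 0.09)
        dlat = rng.uniform(-0.09, 0.09)
        pts = [TrackPoint(T0, lon0, lat0),
               TrackPoint(T0 + timedelta(seconds=5), lon0 + dlon, lat0 + dlat)]
        p = prep.project_to_local(Track("p", "c", T0.date(), pts), camp)
        planar = float(np.hypot(p.x[1] - p.x[0], p.y[1] - p.y[0]))
        ref = prep.haversine_m(lon0, lat0, lon0 + dlon, lat0 + dlat)
        assert planar == pytest.approx(ref, rel=1e-3)


def test_projection_rejects_points_beyond_validity(camp):
    lon0, lat0 = camp.centroid
    track = Track("p", "c", T0.date(), [
        TrackPoint(T0, lon0, lat0), TrackPoint(T0 + timedelta(seconds=5), lon0 + 3.0, lat0),
    ])
    with pytest.raises(ValueError, match="200 km"):
        prep.project_to_local(track, camp)


# ---------------------------------------------------------------------------
# speed filter


def _walking_track(n=200, speed=1.4, interval=5.0):
    x = speed * interval * np.arange(n)
    return make_ptrack(x, np.zeros(n), interval=interval)


def test_clean_walking_track_unchanged():
    p = _walking_track()
    out = prep.filter_speed(p)
    assert len(out) == len(p)
    np.testing.assert_array_equal(out.x, p.x)


def test_teleported_fix_removed_exactly():
    p = _walking_track()
    x = p.x.copy()
    x[100] += 3000.0  # 3 km teleport between 5 s neighbours: 600 m/s implied
    p2 = make_ptrack(x, np.zeros(len(x)))
    out = prep.filter_speed(p2)
    assert len(out) == len(p2) - 1
    assert not np.any(np.isclose(out.x, x[100]))
    # conservation: kept + removed accounts for every input fix
    assert out.log[-1]["removed"] == 1


def test_all_identical_points_unchanged():
    p = make_ptrack(np.full(50, 3.0), np.full(50, 4.0))
    out = prep.filter_speed(p)
    assert len(out) == 50


def test_unusable_track_rejected():
    rng = np.random.default_rng(0)
    # every fix teleports: implied speeds vastly over the ceiling everywhere
    p = make_ptrack(rng.uniform(0, 1e5, 60), rng.uniform(0, 1e5, 60))
    with pytest.raises(ValueError, match="unusable"):
        prep.filter_speed(p)


# ---------------------------------------------------------------------------
# vehicle days


def _track_with_fast_window(fast_speed, fast_duration, interval=5.0):
    walk = 1.4
    n_fast = int(fast_duration / interval)
    speeds = np.concatenate([np.full(200, walk), np.full(n_fast, fast_speed), np.full(200, walk)])
    x = np.concatenate([[0.0], np.cumsum(speeds * interval)])
    return make_ptrack(x, np.zeros(len(x)), interval=interval)


def test_sustained_motorcycle_segment_drops_day():
    p = _track_with_fast_window(8.0, 600.0)  # 10 min at 8 m/s
    keep, evidence = prep.filter_vehicle_day(p)
    assert not keep
    assert evidence["longest_fast_run_s"] >= 600.0


def test_short_running_burst_keeps_day():
    keep, _ = prep.filter_vehicle_day(_track_with_fast_window(4.0, 60.0))
    assert keep


def test_pure_walking_day_kept():
    keep, _ = prep.filter_vehicle_day(_walking_track())
    assert keep


# ---------------------------------------------------------------------------
# resampling


def test_resample_idempotent_on_exact_grid():
    p = _walking_track(interval=5.0)
    out = prep.resample_5s(p)
    np.testing.assert_allclose(out.t, p.t)
    np.testing.assert_allclose(out.x, p.x)
    out2 = prep.resample_5s(out)
    np.testing.assert_allclose(out2.x, out.x)


def test_resample_preserves_length_of_constant_velocity_segment():
    t = np.array([0.0, 7.0, 13.0, 20.0]) + 1.5e9
    x = 1.4 * (t - t[0])
    p = make_ptrack(x, 0.5 * (t - t[0]), t=t)
    out = prep.resample_5s(p)
    assert out.path_length() == pytest.approx(p.path_length(), rel=1e-9)


def test_resample_never_increases_path_length():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = rng.integers(5, 60)
        t = 1.5e9 + np.cumsum(rng.uniform(1, 30, n))
        p = make_ptrack(rng.normal(0, 50, n), rng.normal(0, 50, n), t=t)
        out = prep.resample_5s(p)
        assert out.path_length() <= p.path_length() + 1e-9


def test_resample_flags_long_gaps():
    t = np.array([0.0, 5.0, 400.0, 405.0]) + 1.5e9
    p = make_ptrack([0.0, 7.0, 560.0, 567.0], np.zeros(4), t=t)
    out = prep.resample_5s(p)
    inside = (out.t > t[1]) & (out.t < t[2])
    assert out.gap_filled[inside].all()
    assert not out.gap_filled[~inside].any()


# ---------------------------------------------------------------------------
# in/out of camp and inclusion


def test_classify_in_camp_centre_boundary_and_far(camp):
    poly = prep.project_polygon(camp.boundary, camp)
    vx, vy = poly.exterior.coords[0]
    p = make_ptrack([0.0, vx, 10_000.0], [0.0, vy, 0.0])
    prep.classify_in_camp(p, camp)
    assert p.in_camp[0]       # centroid
    assert p.in_camp[1]       # polygon vertex counts as in
    assert not p.in_camp[2]   # 10 km away


def test_eight_hour_inclusion_boundary():
    short = make_ptrack([0, 1], [0, 0], t=np.array([0.0, 7.99 * 3600]))
    exact = make_ptrack([0, 1], [0, 0], t=np.array([0.0, 8.00 * 3600]))
    kept, n_excl = prep.apply_inclusion([short, exact], min_hours=8.0)
    assert kept == [exact]
    assert n_excl == 1


def test_default_simulated_recording_span_near_11_5_hours(default_study):
    _, sim, result = default_study
    spans = [p.duration_hours for p in result.ptracks]
    assert 11.0 < float(np.mean(spans)) < 12.0


# ---------------------------------------------------------------------------
# daily distance


def test_daily_distance_stationary_and_out_and_back():
    with pytest.warns(UserWarning):
        assert prep.daily_distance(make_ptrack([0.0], [0.0])) == 0.0
    # straight 5 km out and 5 km back at 5 m per fix
    x = np.concatenate([np.arange(0, 5000.0, 5), np.arange(5000.0, -1, -5)])
    p = make_ptrack(x, np.zeros(len(x)))
    assert prep.daily_distance(p) == pytest.approx(10.0, abs=0.05)
    rev = make_ptrack(x[::-1], np.zeros(len(x)))
    assert prep.daily_distance(rev) == pytest.approx(prep.daily_distance(p))


# ---------------------------------------------------------------------------
# bout extraction


def _out_and_back(apex=2000.0, step=10.0):
    out = np.arange(0.0, apex + step, step)
    x = np.concatenate([out, out[::-1][1:]])
    in_camp = np.abs(x) < 100.0
    return make_ptrack(x, np.zeros(len(x)), in_camp=in_camp)


def test_no_bout_when_never_beyond_min_range():
    p = _out_and_back(apex=400.0)
    assert prep.extract_primary_bout(p) is None


def test_single_out_and_back_bout_apex_and_chords():
    p = _out_and_back(apex=2000.0)
    bout = prep.extract_primary_bout(p)
    assert bout is not None
    assert p.dist_from_camp[bout.apex_index] == pytest.approx(2000.0)
    assert bout.max_dist_from_camp == pytest.approx(p.dist_from_camp[bout.start:bout.end + 1].max())
    assert bout.outbound_path_length >= bout.outbound_chord > 0
    assert bout.inbound_path_length >= bout.inbound_chord > 0


def test_longest_of_two_bouts_selected():
    step = 10.0
    leg1 = np.arange(0.0, 1500.0 + step, step)          # 3 km round trip
    leg2 = np.arange(0.0, 3500.0 + step, step)          # 7 km round trip
    x = np.concatenate([leg1, leg1[::-1][1:], [0.0] * 20, leg2, leg2[::-1][1:]])
    p = make_ptrack(x, np.zeros(len(x)), in_camp=np.abs(x) < 100.0)
    bout = prep.extract_primary_bout(p)
    assert bout.max_dist_from_camp == pytest.approx(3500.0)


def test_apex_tie_broken_to_earliest():
    x = np.array([0.0, 600.0, 600.0 - 1e-12, 600.0, 0.0])
    p = make_ptrack(x, np.zeros(5), in_camp=np.array([1, 0, 0, 0, 1], bool))
    bout = prep.extract_primary_bout(p)
    assert bout.apex_index == 1
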