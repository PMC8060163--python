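"""Supercover rasterization, land metrics, segregation and MCPs."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from conftest import make_ptrack
from foragerpath.raster import (
    CellSet,
    cells_traversed,
    cumulative_land_explored,
    daily_land_visited,
    gender_segregation,
    mcp_area,
    supercover_cells,
)
from foragerpath.trackio import GridSpec, PersonMeta

GRID = GridSpec(cell_size=10.0)


def shapely_supercover(x, y, grid):
    """Independent oracle: every cell whose closed square the polyline meets."""
    s = grid.cell_size
    ox, oy = grid.origin
    cells = set()
    for k in range(len(x) - 1):
        seg = (
            LineString([(x[k], y[k]), (x[k + 1], y[k + 1])])
            if (x[k], y[k]) != (x[k + 1], y[k + 1])
            else Point(x[k], y[k])
        )
        imin = int(np.floor((min(x[k], x[k + 1]) - ox) / s))
        imax = int(np.floor((max(x[k], x[k + 1]) - ox) / s))
        jmin = int(np.floor((min(y[k], y[k + 1]) - oy) / s))
        jmax = int(np.floor((max(y[k], y[k + 1]) - oy) / s))
        for i in range(imin, imax + 1):
            for j in range(jmin, jmax + 1):
                sq = box(ox + i * s, oy + j * s, ox + (i + 1) * s, oy + (j + 1) * s)
                if sq.intersects(seg):
                    cells.add((i, j))
    if len(x) == 1:
        cells.add((int(np.floor((x[0] - ox) / s)), int(np.floor((y[0] - oy) / s))))
    return cells


def test_stationary_point_occupies_its_cell():
    assert supercover_cells([5.0], [5.0], GRID) == {(0, 0)}


def test_horizontal_segment_covers_three_cells():
    assert supercover_cells([5.0, 25.0], [5.0, 5.0], GRID) == {(0, 0), (1, 0), (2, 0)}


def test_corner_touching_cells_included():
    # diagonal through the exact grid corner (10, 10) touches all four cells
    cells = supercover_cells([5.0, 15.0], [5.0, 15.0], GRID)
    assert cells == {(0, 0), (1, 1), (0, 1), (1, 0)}


def test_supercover_matches_geometric_oracle_on_random_segments():
    rng = np.random.default_rng(42)
    for _ in range(300):
        x = rng.uniform(-40, 40, 2)
        y = rng.uniform(-40, 40, 2)
        assert supercover_cells(x, y, GRID) == shapely_supercover(x, y, GRID)


def test_supercover_contains_every_point_cell_and_is_reversal_stable():
    rng = np.random.default_rng(1)
    x = np.cumsum(rng.normal(0, 8, 50))
    y = np.cumsum(rng.normal(0, 8, 50))
    cells = supercover_cells(x, y, GRID)
    for px, py in zip(x, y):
        assert (int(np.floor(px / 10)), int(np.floor(py / 10))) in cells
    assert cells == supercover_cells(x[::-1], y[::-1], GRID)


def test_centimetre_sampling_cells_are_subset_of_supercover():
    rng = np.random.default_rng(8)
    for _ in range(50):
        x = rng.uniform(-30, 30, 2)
        y = rng.uniform(-30, 30, 2)
        cover = supercover_cells(x, y, GRID)
        length = float(np.hypot(x[1] - x[0], y[1] - y[0]))
        t = np.linspace(0, 1, max(int(length / 0.01), 2))
        sx = x[0] + t * (x[1] - x[0])
        sy = y[0] + t * (y[1] - y[0])
        sampled = set(zip(np.floor(sx / 10).astype(int).tolist(),
                          np.floor(sy / 10).astype(int).tolist()))
        assert sampled <= cover


def _cellset(cells, owner=("p", "d1")):
    return CellSet(owner=owner, cells=frozenset(cells), grid=GRID)


def test_daily_land_visited_is_cell_count_times_area():
    assert daily_land_visited(_cellset({(i, 0) for i in range(50)})) == 5000.0
    assert daily_land_visited(_cellset(set())) == 0.0


def test_cumulative_land_explored_worked_two_day_example():
    day1 = _cellset({(i, 0) for i in range(50)})                 # 50 cells
    day2 = _cellset({(i, 0) for i in range(40, 100)})            # 60 cells, 50 new
    cum = cumulative_land_explored([day1, day2])
    assert daily_land_visited(day1) == 5000.0
    assert daily_land_visited(day2) == 6000.0
    assert list(cum) == [5000.0, 10000.0]


def test_cumulative_properties():
    days = [_cellset({(0, 0), (1, 0)}), _cellset({(0, 0), (1, 0)})]
    cum = cumulative_land_explored(days)
    assert list(cum) == [200.0, 200.0]  # identical days: constant
    assert cum[0] == daily_land_visited(days[0])
    rng = np.random.default_rng(0)
    days = [
        _cellset({(int(a), int(b)) for a, b in rng.integers(0, 10, (20, 2))})
        for _ in range(6)
    ]
    cum = cumulative_land_explored(days)
    assert (np.diff(cum) >= 0).all()
    assert cum[-1] <= sum(daily_land_visited(d) for d in days)


def test_mixed_grids_rejected():
    other = CellSet(owner=("p", "d"), cells=frozenset({(0, 0)}), grid=GridSpec(cell_size=20.0))
    with pytest.raises(ValueError, match="grid"):
        cumulative_land_explored([_cellset({(0, 0)}), other])


PERSONS = {
    "m1": PersonMeta("m1", "male", 30, False, "c"),
    "f1": PersonMeta("f1", "female", 30, False, "c"),
}


def test_segregation_hand_example():
    cs = [
        CellSet(("m1", "d"), frozenset({(0, 0), (1, 0), (2, 0)}), GRID),  # {A,B,C}
        CellSet(("f1", "d"), frozenset({(2, 0), (3, 0)}), GRID),          # {C,D}
    ]
    seg = gender_segregation(cs, PERSONS)
    assert seg.total_km2 == pytest.approx(4 * 100 / 1e6)
    assert seg.both_km2 == pytest.approx(100 / 1e6)
    assert seg.overlap_pct == pytest.approx(25.0)
    # conservation, exact in cell counts
    assert seg.male_km2 + seg.female_km2 - seg.both_km2 == pytest.approx(seg.total_km2)


def test_segregation_disjoint_and_identical():
    disjoint = [
        CellSet(("m1", "d"), frozenset({(0, 0)}), GRID),
        CellSet(("f1", "d"), frozenset({(5, 5)}), GRID),
    ]
    seg = gender_segregation(disjoint, PERSONS)
    assert seg.both_km2 == 0.0 and seg.overlap_pct == 0.0
    same = [
        CellSet(("m1", "d"), frozenset({(0, 0), (1, 1)}), GRID),
        CellSet(("f1", "d"), frozenset({(0, 0), (1, 1)}), GRID),
    ]
    seg = gender_segregation(same, PERSONS)
    assert seg.male_female_ratio == pytest.approx(1.0)
    assert seg.overlap_pct == pytest.approx(100.0)


def test_segregation_requires_both_genders():
    with pytest.raises(ValueError, match="gender"):
        gender_segregation([CellSet(("m1", "d"), frozenset({(0, 0)}), GRID)], PERSONS)


# ---------------------------------------------------------------------------
# MCP


def test_mcp_full_fraction_square():
    pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [5, 5]], dtype=float)
    _, area = mcp_area(pts, fraction=1.0)
    assert area == pytest.approx(100.0 / 1e6)


def test_mcp_outliers_excluded_at_95_percent():
    rng = np.random.default_rng(0)
    inner = rng.uniform(0, 1, (95, 2))
    outliers = 10_000.0 * np.ones((5, 2)) * rng.choice([-1, 1], (5, 2))
    pts = np.vstack([inner, outliers])
    _, area95 = mcp_area(pts, fraction=0.95)
    _, area_inner = mcp_area(inner, fraction=1.0)
    assert area95 == pytest.approx(area_inner)


def test_mcp_monotone_in_fraction():
    rng = np.random.default_rng(5)
    pts = rng.normal(0, 100, (200, 2))
    _, a100 = mcp_area(pts, fraction=1.0)
    _, a95 = mcp_area(pts, fraction=0.95)
    assert a100 >= a95


def test_mcp_collinear_degenerate():
    pts = np.column_stack([np.arange(6.0), np.arange(6.0)])
    with pytest.warns(UserWarning, match="degenerate"):
        _, area = mcp_area(pts, fraction=1.0)
    assert area == 0.0


# ---------------------------------------------------------------------------
# grid-origin sensitivity (documented comparability caveat)


def test_daily_area_insensitive_to_grid_origin():
    """Jittering the raster anchor changes a day's area by well under 5% CV."""
    rng = np.random.default_rng(9)
    x = np.cumsum(rng.normal(0.8, 2.0, 4000))
    y = np.cumsum(rng.normal(0.2, 2.0, 4000))
    p = make_ptrack(x, y)
    areas = []
    for _ in range(15):
        ox, oy = rng.uniform(0, 10, 2)
        grid = GridSpec(cell_size=10.0, origin=(ox, oy))
        areas.append(daily_land_visited(cells_traversed(p, grid)))
    areas = np.array(areas)
    assert areas.std() / areas.mean() < 0.05
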