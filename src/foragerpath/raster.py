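"""Raster measures of land visitation, gender segregation and MCP home ranges.

The landscape around a camp is modelled as a square grid (default 10 m x
10 m cells, area A = 100 m^2 per cell) anchored at the camp centroid.  A
person-day's *cell set* is every cell whose closed square the track
geometrically intersects (supercover rasterization, corner touches
included).  Cell counts drive:

* daily land visited      = |cells on day i| * A
* cumulative land explored = |union of cells, days 1..i| * A
* geographic segregation   = male-only / female-only / both-gender partition

Minimum convex polygons (MCPs) follow the conventional home-range recipe:
drop the fraction of points farthest from the centroid, hull the rest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .preprocess import ProjectedTrack
from .trackio import GridSpec, PersonMeta


@dataclass(frozen=True)
class CellSet:
    """Set of visited grid cells for one person-day."""

    owner: tuple[str, object]  # (person_id, date)
    cells: frozenset[tuple[int, int]]
    grid: GridSpec

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class SegregationSummary:
    """Male/female/both partition of the land visited in one camp."""

    camp_id: str
    total_km2: float
    male_km2: float
    female_km2: float
    both_km2: float
    male_female_ratio: float | None
    overlap_pct: float


# ---------------------------------------------------------------------------
# supercover rasterization


def _segment_box_mask(
    x0: np.ndarray, y0: np.ndarray, x1: np.ndarray, y1: np.ndarray,
    ci: np.ndarray, cj: np.ndarray,
) -> np.ndarray:
    """Closed-box Liang-Barsky test: does segment k intersect cell (ci, cj)?

    Coordinates are in cell units; the candidate box is [ci, ci+1] x [cj, cj+1]
    (closed, so corner and edge touches count).
    """
    tmin = np.zeros_like(x0)
    tmax = np.ones_like(x0)
    for p0, p1, lo in ((x0, x1, ci), (y0, y1, cj)):
        d = p1 - p0
        hi = lo + 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo - p0) / d
            t2 = (hi - p0) / d
        tlo = np.minimum(t1, t2)
        thi = np.maximum(t1, t2)
        par = d == 0.0
        inside = (p0 >= lo) & (p0 <= hi)
        tmin = np.where(par, np.where(inside, tmin, np.inf), np.maximum(tmin, tlo))
        tmax = np.where(par, np.where(inside, tmax, -np.inf), np.minimum(tmax, thi))
    return tmin <= tmax


def supercover_cells(
    x: np.ndarray, y: np.ndarray, grid: GridSpec
) -> set[tuple[int, int]]:
    """All cells whose closed square a polyline intersects.

    For each consecutive point pair every candidate cell in the segment's
    bounding box is tested against the closed cell square, so grazing and
    corner-touching cells are included.  Cell (i, j) covers the half-open
    square [ox + i*s, ox + (i+1)*s) x [oy + j*s, oy + (j+1)*s); its *closed*
    square is used for the intersection test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        return set()
    s = grid.cell_size
    ox, oy = grid.origin
    u = (x - ox) / s
    v = (y - oy) / s
    pi = np.floor(u).astype(np.int64)
    pj = np.floor(v).astype(np.int64)
    cells: set[tuple[int, int]] = set(zip(pi.tolist(), pj.tolist()))
    if x.size == 1:
        return cells
    u0, u1 = u[:-1], u[1:]
    v0, v1 = v[:-1], v[1:]
    imin = np.floor(np.minimum(u0, u1)).astype(np.int64)
    imax = np.floor(np.maximum(u0, u1)).astype(np.int64)
    jmin = np.floor(np.minimum(v0, v1)).astype(np.int64)
    jmax = np.floor(np.maximum(v0, v1)).astype(np.int64)
    ni = imax - imin + 1
    nj = jmax - jmin + 1
    ncand = ni * nj
    multi = ncand > 1  # single-cell segments already collected via endpoints
    if not multi.any():
        return cells
    idx = np.nonzero(multi)[0]
    counts = ncand[idx]
    rep = np.repeat(idx, counts)
    # offset within each segment's candidate block
    offs = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    cand_i = imin[rep] + offs // nj[rep]
    cand_j = jmin[rep] + offs % nj[rep]
    hit = _segment_box_mask(u0[rep], v0[rep], u1[rep], v1[rep],
                            cand_i.astype(float), cand_j.astype(float))
    cells.update(zip(cand_i[hit].tolist(), cand_j[hit].tolist()))
    return cells


def cells_traversed(ptrack: ProjectedTrack, grid: GridSpec) -> CellSet:
    """Supercover cell set of a (resampled, projected) person-day track."""
    cells = supercover_cells(ptrack.x, ptrack.y, grid)
    return CellSet(owner=(ptrack.person_id, ptrack.date), cells=frozenset(cells), grid=grid)


# ---------------------------------------------------------------------------
# land metrics


def daily_land_visited(cs: CellSet) -> float:
    """Daily land visited in m^2: number of unique cells times cell area A."""
    return len(cs.cells) * cs.grid.area_m2


def cumulative_land_explored(daily_cellsets: Sequence[CellSet]) -> np.ndarray:
    """Cumulative land explored in m^2 at each day index (non-decreasing).

    Value at day i is the size of the union of the cell sets of days 1..i
    times the cell area.
    """
    if not daily_cellsets:
        return np.array([])
    grid = daily_cellsets[0].grid
    if any(cs.grid != grid for cs in daily_cellsets):
        raise ValueError("all cell sets must share one grid")
    seen: set[tuple[int, int]] = set()
    out = np.empty(len(daily_cellsets))
    for k, cs in enumerate(daily_cellsets):
        seen |= cs.cells
        out[k] = len(seen) * grid.area_m2
    return out


def gender_segregation(
    cellsets: Iterable[CellSet],
    persons: Mapping[str, PersonMeta],
    camp_id: str = "camp",
) -> SegregationSummary:
    """Partition the land visited in a camp into male / female / both areas.

    A cell counts as visited by a gender if at least one person of that
    gender traversed it on any day.  Areas come from exact cell counts, so
    male + female - both = total holds exactly.
    """
    male: set[tuple[int, int]] = set()
    female: set[tuple[int, int]] = set()
    area = None
    for cs in cellsets:
        pid = cs.owner[0]
        gender = persons[pid].gender
        (male if gender == "male" else female).update(cs.cells)
        area = cs.grid.area_m2
    if not male or not female:
        raise ValueError(
            f"camp {camp_id}: need tracks from both genders for segregation "
            "(extremely gender-imbalanced camps are excluded)"
        )
    both = male & female
    total = male | female
    to_km2 = area / 1e6
    total_km2 = len(total) * to_km2
    female_km2 = len(female) * to_km2
    return SegregationSummary(
        camp_id=camp_id,
        total_km2=total_km2,
        male_km2=len(male) * to_km2,
        female_km2=female_km2,
        both_km2=len(both) * to_km2,
        male_female_ratio=(len(male) / len(female)) if female else None,
        overlap_pct=100.0 * len(both) / len(total),
    )


# ---------------------------------------------------------------------------
# minimum convex polygon


def mcp_area(
    points: np.ndarray, fraction: float = 0.95
) -> tuple[np.ndarray | None, float]:
    """Minimum convex polygon home range.

    Discards the ``ceil((1 - fraction) * n)`` points farthest from the
    points' centroid (Euclidean), hulls the rest and returns
    ``(hull_vertices, area_km2)``.  Collinear point sets yield area 0 with a
    degenerate-hull warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar coordinates")
    n = len(pts)
    if n < 5:
        raise ValueError(f"MCP needs at least 5 points, got {n}")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n_drop = math.ceil((1.0 - fraction) * n - 1e-9)  # guard float fuzz in (1 - fraction)
    if n_drop:
        centroid = pts.mean(axis=0)
        d = np.hypot(*(pts - centroid).T)
        keep = np.argsort(d, kind="stable")[: n - n_drop]
        pts = pts[keep]
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("degenerate (collinear) point set; MCP area is 0", stacklevel=2)
        return None, 0.0
    # for 2-D hulls, `volume` is the polygon area
    return pts[hull.vertices], hull.volume / 1e6
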