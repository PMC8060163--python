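"""Path sinuosity: outbound/inbound bout measures and the geographically
weighted per-cell score.

Sinuosity (tortuosity) is the ratio of the distance actually travelled
between two locations to the straight-line ("as the crow flies") distance
between them; it is >= 1 by the triangle inequality, with 1 meaning a
perfectly direct route.

Two granularities are computed:

* **Bout sinuosity** — the day's principal out-of-camp excursion is split at
  its apex (farthest point from the camp centroid) into an outbound and an
  inbound segment, and each segment's path length is divided by its chord.
* **Geographically weighted sinuosity** — out-of-camp travel is segmented by
  the 10 m grid; each *pass* through a cell (entry to exit, chords clipped
  to the cell boundary) gets a sinuosity, cells average their passes, and a
  track is scored by how many of its cells exceed the population mean
  ("high") or the population 99th percentile ("very high"), both with strict
  inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Bout, ProjectedTrack
from .trackio import GridSpec

#: Chords shorter than this (metres) are treated as degenerate (loops/dwells).
CHORD_EPS = 1.0


@dataclass
class SinuosityRecord:
    person_id: str
    date: object
    outbound: float
    inbound: float


@dataclass
class CellSinuosityField:
    """Per-cell mean pass sinuosity for one track, with threshold counts."""

    grid: GridSpec
    cell_means: dict[tuple[int, int], float]
    n_high: int | None = None
    n_very_high: int | None = None


def path_sinuosity(points: np.ndarray, chord_eps: float = CHORD_EPS) -> float:
    """Path length divided by the straight-line distance between endpoints.

    Returns NaN for degenerate chords (endpoints closer than ``chord_eps``,
    e.g. closed loops), which callers must exclude.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least two planar points")
    length = float(np.hypot(*np.diff(pts, axis=0).T).sum())
    chord = float(np.hypot(*(pts[-1] - pts[0])))
    if chord < chord_eps:
        return float("nan")
    return length / chord


def bout_sinuosity(
    ptrack: ProjectedTrack,
    bout: Bout,
    chord_eps: float = CHORD_EPS,
    max_gap_fraction: float = 0.2,
) -> SinuosityRecord | None:
    """Outbound and inbound sinuosity of a primary bout.

    Segments bridged across recording gaps are excluded from the path
    lengths; a bout with more than ``max_gap_fraction`` gap-filled points is
    skipped entirely (a straight interpolation bridge would bias sinuosity
    toward 1).  Degenerate chords also skip the record.
    """
    if bout.gap_fraction > max_gap_fraction:
        ptrack.log.append({"op": "bout_sinuosity", "skip": "gap_fraction",
                           "gap_fraction": bout.gap_fraction})
        return None
    if bout.outbound_chord < chord_eps or bout.inbound_chord < chord_eps:
        ptrack.log.append({"op": "bout_sinuosity", "skip": "degenerate_chord"})
        return None
    gap = ptrack.gap_filled
    seg = ptrack.segment_lengths()
    seg_ok = ~(gap[:-1] | gap[1:])  # drop segments touching a gap-filled fix
    out_len = float((seg[bout.start:bout.apex_index] * seg_ok[bout.start:bout.apex_index]).sum())
    in_len = float((seg[bout.apex_index:bout.end] * seg_ok[bout.apex_index:bout.end]).sum())
    return SinuosityRecord(
        person_id=ptrack.person_id,
        date=ptrack.date,
        outbound=out_len / bout.outbound_chord,
        inbound=in_len / bout.inbound_chord,
    )


# ---------------------------------------------------------------------------
# geographically weighted sinuosity


def _clip_t(p0x: float, p0y: float, p1x: float, p1y: float,
            i: int, j: int) -> tuple[float, float]:
    """Liang-Barsky parameter range of a segment inside closed cell [i,i+1]x[j,j+1]
    (cell units)."""
    tmin, tmax = 0.0, 1.0
    for p0, p1, lo in ((p0x, p1x, float(i)), (p0y, p1y, float(j))):
        d = p1 - p0
        hi = lo + 1.0
        if d == 0.0:
            if not (lo <= p0 <= hi):
                return 1.0, 0.0
        else:
            t1, t2 = (lo - p0) / d, (hi - p0) / d
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
    return tmin, tmax


def cell_pass_sinuosities(
    ptrack: ProjectedTrack,
    grid: GridSpec,
    chord_eps: float = CHORD_EPS,
) -> dict[tuple[int, int], list[float]]:
    """Sinuosity of every pass through every cell of a track's out-of-camp travel.

    A pass is a maximal run of consecutive out-of-camp fixes sharing one
    containing cell, extended to the boundary-crossing points of the entry
    and exit segments.  Pass sinuosity is the in-cell path length divided by
    the entry-to-exit chord; dwell-only passes with chord < ``chord_eps``
    are skipped.  Gap-filled fixes break passes.
    """
    if ptrack.in_camp is None:
        raise ValueError("classify_in_camp must run before geographically weighted sinuosity")
    s = grid.cell_size
    ox, oy = grid.origin
    u = (ptrack.x - ox) / s
    v = (ptrack.y - oy) / s
    ci = np.floor(u).astype(np.int64)
    cj = np.floor(v).astype(np.int64)
    usable = (~ptrack.in_camp) & (~ptrack.gap_filled)
    passes: dict[tuple[int, int], list[float]] = {}
    n = len(ptrack)
    k = 0
    while k < n:
        if not usable[k]:
            k += 1
            continue
        # maximal usable run with constant cell
        m = k
        while m + 1 < n and usable[m + 1] and ci[m + 1] == ci[k] and cj[m + 1] == cj[k]:
            m += 1
        cell = (int(ci[k]), int(cj[k]))
        # in-run path length (cell units)
        du = np.diff(u[k:m + 1])
        dv = np.diff(v[k:m + 1])
        length = float(np.hypot(du, dv).sum())
        # entry point: clip the approach segment (k-1 -> k) to the cell
        ex, ey = u[k], v[k]
        if k > 0 and usable[k - 1]:
            tmin, _ = _clip_t(u[k - 1], v[k - 1], u[k], v[k], *cell)
            if tmin <= 1.0:
                ex = u[k - 1] + tmin * (u[k] - u[k - 1])
                ey = v[k - 1] + tmin * (v[k] - v[k - 1])
                length += float(np.hypot(u[k] - ex, v[k] - ey))
        # exit point: clip the departure segment (m -> m+1) to the cell
        qx, qy = u[m], v[m]
        if m + 1 < n and usable[m + 1]:
            _, tmax = _clip_t(u[m], v[m], u[m + 1], v[m + 1], *cell)
            if tmax >= 0.0:
                qx = u[m] + tmax * (u[m + 1] - u[m])
                qy = v[m] + tmax * (v[m + 1] - v[m])
                length += float(np.hypot(qx - u[m], qy - v[m]))
        chord = float(np.hypot(qx - ex, qy - ey))
        if chord * s >= chord_eps:
            passes.setdefault(cell, []).append((length / chord) if chord else float("inf"))
        k = m + 1
    return passes


def cell_sinuosity_field(
    ptrack: ProjectedTrack, grid: GridSpec, chord_eps: float = CHORD_EPS
) -> CellSinuosityField:
    """Per-cell mean pass sinuosity for one track (unscored)."""
    passes = cell_pass_sinuosities(ptrack, grid, chord_eps)
    means = {cell: float(np.mean(vals)) for cell, vals in passes.items()}
    return CellSinuosityField(grid=grid, cell_means=means)


def population_cell_stats(
    fields: list[CellSinuosityField],
) -> tuple[float, float, int]:
    """Population mean and 99th percentile over all cell values of all tracks.

    Returns ``(mean, p99, n_cells)``.  Computed once per analysis run and
    reused to score every track, so per-track scoring is reproducible.
    """
    values = np.array([val for f in fields for val in f.cell_means.values()])
    if values.size == 0:
        return float("nan"), float("nan"), 0
    return float(values.mean()), float(np.percentile(values, 99)), int(values.size)


def score_field(
    field: CellSinuosityField, population_mean: float, population_p99: float
) -> CellSinuosityField:
    """Count a track's high / very-high sinuosity cells (strict inequality)."""
    vals = np.array(list(field.cell_means.values()))
    field.n_high = int((vals > population_mean).sum())
    field.n_very_high = int((vals > population_p99).sum())
    return field
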