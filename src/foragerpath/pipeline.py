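"""End-to-end orchestration: simulate/load -> clean -> metrics -> summaries.

This module wires the per-module operations into the standard analysis run
and returns tidy tables.  It is the programmatic equivalent of running the
CLI subcommands in sequence, and the single entry point used by the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess as prep
from . import raster, sinuosity, sociality, stats
from .simulate import SimConfig, SimResult, simulate_camp
from .trackio import CampContext, PersonMeta, Track


@dataclass
class PipelineResult:
    per_day: pd.DataFrame            # person-day metrics (model-ready)
    segregation: raster.SegregationSummary | None
    mcp: pd.DataFrame                # MCP area by gender
    sociality: pd.DataFrame          # pooled proximity sample
    proximity_curve: pd.DataFrame
    gw_population: tuple[float, float, int]   # (mean, p99, n_cells)
    excluded: dict = field(default_factory=dict)
    ptracks: list = field(default_factory=list)


def clean_track(track: Track, camp: CampContext) -> tuple[prep.ProjectedTrack | None, str]:
    """Project, resample, vehicle-screen, despike and label one person-day.

    Returns ``(ptrack, reason)`` where ``ptrack`` is None when the day is
    dropped (vehicle travel, unusable fix quality).
    """
    p = prep.project_to_local(track, camp)
    p = prep.resample_5s(p)
    keep, _ = prep.filter_vehicle_day(p)
    if not keep:
        return None, "vehicle_day"
    try:
        p = prep.filter_speed(p)
    except ValueError:
        return None, "speed_filter_unusable"
    p = prep.classify_in_camp(p, camp)
    return p, "ok"


def run_pipeline(
    tracks: list[Track],
    persons: list[PersonMeta],
    camp: CampContext,
    seed: int = 0,
    min_hours: float = 8.0,
    sociality_n: int = 100,
) -> PipelineResult:
    """The full analysis on a set of person-day tracks from one camp."""
    persons_by_id = {p.person_id: p for p in persons}
    cleaned: list[prep.ProjectedTrack] = []
    excluded = {"vehicle_day": 0, "speed_filter_unusable": 0, "short_recording": 0}
    for tr in tracks:
        p, reason = clean_track(tr, camp)
        if p is None:
            excluded[reason] += 1
            continue
        cleaned.append(p)
    cleaned, n_short = prep.apply_inclusion(cleaned, min_hours=min_hours)
    excluded["short_recording"] = n_short

    # --- per-day land and distance metrics
    grid = camp.grid
    cellsets: dict[str, list[tuple[object, raster.CellSet]]] = {}
    rows = []
    fields = []
    bouts: dict[tuple[str, object], sinuosity.SinuosityRecord | None] = {}
    for p in cleaned:
        cs = raster.cells_traversed(p, grid)
        cellsets.setdefault(p.person_id, []).append((p.date, cs))
        bout = prep.extract_primary_bout(p)
        rec = sinuosity.bout_sinuosity(p, bout) if bout is not None else None
        bouts[(p.person_id, p.date)] = rec
        fields.append(sinuosity.cell_sinuosity_field(p, grid))
        rows.append(
            {
                "person_id": p.person_id,
                "date": p.date,
                "daily_km": prep.daily_distance(p),
                "daily_m2": raster.daily_land_visited(cs),
                "outbound": rec.outbound if rec else np.nan,
                "inbound": rec.inbound if rec else np.nan,
            }
        )
    per_day = pd.DataFrame(rows)

    # cumulative land explored per person, in day order
    if not per_day.empty:
        cum = {}
        for pid, day_sets in cellsets.items():
            day_sets.sort(key=lambda t: str(t[0]))
            values = raster.cumulative_land_explored([cs for _, cs in day_sets])
            for (d, _), v in zip(day_sets, values):
                cum[(pid, d)] = v
        per_day["cumulative_m2"] = [
            cum[(r.person_id, r.date)] for r in per_day.itertuples()
        ]
        per_day["day_index"] = per_day.groupby("person_id")["date"].rank(method="dense").astype(int)
        per_day["gender"] = per_day["person_id"].map(lambda i: persons_by_id[i].gender)

    # --- geographically weighted sinuosity population stats + per-track scores
    gw_stats = sinuosity.population_cell_stats(fields)
    pop_mean, pop_p99, _ = gw_stats
    if not per_day.empty:
        scored = [sinuosity.score_field(f, pop_mean, pop_p99) for f in fields]
        per_day["n_high"] = [f.n_high for f in scored]
        per_day["n_very_high"] = [f.n_very_high for f in scored]

    # --- gender segregation and MCP by gender
    all_cellsets = [cs for sets in cellsets.values() for _, cs in sets]
    try:
        seg = raster.gender_segregation(all_cellsets, persons_by_id, camp_id=camp.camp_id)
    except ValueError:
        seg = None
    mcp_rows = []
    for gender in ("male", "female"):
        pts = [
            np.column_stack([p.x, p.y])
            for p in cleaned
            if persons_by_id[p.person_id].gender == gender
        ]
        if pts:
            stacked = np.vstack(pts)
            _, area = raster.mcp_area(stacked, fraction=0.95)
            mcp_rows.append({"gender": gender, "mcp_km2": area, "n_points": len(stacked)})
    mcp = pd.DataFrame(mcp_rows)

    # --- sociality sample per camp-day
    by_day: dict[object, list[prep.ProjectedTrack]] = {}
    for p in cleaned:
        by_day.setdefault(p.date, []).append(p)
    soc_parts = [
        sociality.sociality_table(day_tracks, persons_by_id, n=sociality_n, seed=seed)
        for day_tracks in by_day.values()
        if len(day_tracks) >= 2
    ]
    soc = pd.concat(soc_parts, ignore_index=True) if soc_parts else pd.DataFrame()
    curve = sociality.proximity_by_distance_curve(soc) if len(soc) else pd.DataFrame()

    return PipelineResult(
        per_day=per_day,
        segregation=seg,
        mcp=mcp,
        sociality=soc,
        proximity_curve=curve,
        gw_population=gw_stats,
        excluded=excluded,
        ptracks=cleaned,
    )


def run_synthetic_study(config: SimConfig) -> tuple[SimResult, PipelineResult]:
    """Simulate a camp under ``config`` and run the full pipeline on it."""
    sim = simulate_camp(config)
    result = run_pipeline(sim.tracks, sim.persons, sim.camp, seed=config.seed)
    return sim, result
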