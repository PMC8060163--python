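"""Shared fixtures: synthetic study run, camp geometry, track builders."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from foragerpath.pipeline import run_synthetic_study
from foragerpath.preprocess import ProjectedTrack
from foragerpath.simulate import SimConfig, make_circular_camp


def make_ptrack(
    x,
    y,
    t=None,
    interval: float = 5.0,
    in_camp=None,
    gap_filled=None,
    person_id: str = "p0",
    day=date(2018, 7, 1),
) -> ProjectedTrack:
    """Hand-built projected track for unit fixtures (camp centroid at origin)."""
    x = np.asarray(x, dtype=float)
    if t is None:
        t = 1_530_000_000.0 + interval * np.arange(len(x))
    p = ProjectedTrack(person_id, "camp", day, np.asarray(t, float), x, np.asarray(y, float))
    if in_camp is not None:
        p.in_camp = np.asarray(in_camp, dtype=bool)
    if gap_filled is not None:
        p.gap_filled = np.asarray(gap_filled, dtype=bool)
    return p


@pytest.fixture(scope="session")
def camp():
    return make_circular_camp(radius_m=150.0)


@pytest.fixture(scope="session")
def default_study():
    """The default gendered synthetic study: ~50 person-days per gender.

    10 men (14 km/day, low heading concentration, solitary) and 10 women
    (8 km/day, high concentration, parties of four spaced ~3 m), 5 days.
    """
    config = SimConfig(n_persons=10, n_days=5, seed=1)
    sim, result = run_synthetic_study(config)
    return config, sim, result
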