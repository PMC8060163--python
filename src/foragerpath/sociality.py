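"""Interindividual proximity while travelling out of camp.

The *sociality sample* is a stratified random subsample of out-of-camp
fixes: up to 100 per person-day (all of them when fewer exist).  Each
sampled fix is annotated with the distance to the nearest neighbour among
all other tracked individuals having a fix within +/-60 s, an indicator for
being within 5 m of that neighbour (inclusive), and the number of
individuals contributing a concurrent fix.  The resulting tidy table is the
input for downstream proximity models; a binned empirical probability curve
by distance from camp is provided as a descriptive summary.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ProjectedTrack
from .trackio import PersonMeta

#: Proximity threshold, metres ("within 5 m" is inclusive: <= 5.0).
NEAR_THRESHOLD_M = 5.0

#: Concurrency window for neighbour fixes, seconds.
TIME_WINDOW_S = 60.0


def draw_sociality_sample(
    ptrack: ProjectedTrack, n: int = 100, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Indices of up to ``n`` out-of-camp fixes, sampled uniformly without
    replacement (all of them if fewer than ``n`` exist)."""
    if ptrack.in_camp is None:
        raise ValueError("classify_in_camp must run before sociality sampling")
    out_idx = np.nonzero(~ptrack.in_camp)[0]
    if len(out_idx) <= n:
        return out_idx
    rng = np.random.default_rng() if rng is None else rng
    return np.sort(rng.choice(out_idx, size=n, replace=False))


def nearest_neighbour(
    t_sample: float,
    x_sample: float,
    y_sample: float,
    others: Sequence[ProjectedTrack],
    window: float = TIME_WINDOW_S,
) -> tuple[float, int]:
    """Nearest-neighbour distance at one sampled instant.

    For each other individual, their temporally closest fix within
    ``+/-window`` seconds (if any) contributes a candidate planar distance;
    the minimum over individuals is returned with the count of contributing
    individuals.  Returns ``(nan, 0)`` when nobody has a concurrent fix.
    """
    best = float("inf")
    n_concurrent = 0
    for other in others:
        k = int(np.searchsorted(other.t, t_sample))
        cand = [i for i in (k - 1, k) if 0 <= i < len(other.t)]
        if not cand:
            continue
        i = min(cand, key=lambda i: abs(other.t[i] - t_sample))
        if abs(other.t[i] - t_sample) > window:
            continue
        n_concurrent += 1
        d = float(np.hypot(other.x[i] - x_sample, other.y[i] - y_sample))
        best = min(best, d)
    return (best, n_concurrent) if n_concurrent else (float("nan"), 0)


def sociality_table(
    ptracks: Sequence[ProjectedTrack],
    persons: Mapping[str, PersonMeta],
    n: int = 100,
    seed: int = 0,
    window: float = TIME_WINDOW_S,
    threshold: float = NEAR_THRESHOLD_M,
) -> pd.DataFrame:
    """Build the sociality sample for one camp-day's set of tracked people.

    Columns: ``person_id, gender, age, timestamp, dist_from_camp_m,
    nn_dist_m, within_5m, n_concurrent``.  Deterministic given ``seed``.
    """
    if len(ptracks) < 2:
        raise ValueError("need at least two tracked individuals in the camp-day")
    rows = []
    for pt in sorted(ptracks, key=lambda p: p.person_id):
        rng = np.random.default_rng([seed, abs(hash_person(pt.person_id))])
        others = [o for o in ptracks if o.person_id != pt.person_id]
        idx = draw_sociality_sample(pt, n=n, rng=rng)
        meta = persons[pt.person_id]
        dist = pt.dist_from_camp
        for i in idx:
            nn, n_conc = nearest_neighbour(pt.t[i], pt.x[i], pt.y[i], others, window)
            rows.append(
                {
                    "person_id": pt.person_id,
                    "gender": meta.gender,
                    "age": meta.age,
                    "timestamp": pt.t[i],
                    "dist_from_camp_m": float(dist[i]),
                    "nn_dist_m": nn,
                    "within_5m": (nn <= threshold) if np.isfinite(nn) else np.nan,
                    "n_concurrent": n_conc,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["person_id", "gender", "age", "timestamp", "dist_from_camp_m",
                 "nn_dist_m", "within_5m", "n_concurrent"],
    )


def hash_person(person_id: str) -> int:
    """Stable non-negative hash of a person id (process-independent)."""
    import zlib

    return zlib.crc32(str(person_id).encode("utf-8"))


def proximity_by_distance_curve(
    table: pd.DataFrame, bin_width: float = 1000.0
) -> pd.DataFrame:
    """Empirical P(within 5 m) by gender and distance-from-camp bin.

    Returns one row per (gender, bin) with the point estimate ``p``, its
    binomial standard error sqrt(p(1-p)/n) and the sample count ``n``.
    Bins without observations are simply absent.
    """
    df = table.dropna(subset=["within_5m"]).copy()
    df["bin"] = np.floor(df["dist_from_camp_m"] / bin_width).astype(int)
    out = []
    for (gender, b), grp in df.groupby(["gender", "bin"]):
        p = float(grp["within_5m"].astype(float).mean())
        n = len(grp)
        out.append(
            {
                "gender": gender,
                "bin_low_m": b * bin_width,
                "bin_high_m": (b + 1) * bin_width,
                "p_within_5m": p,
                "se": float(np.sqrt(p * (1 - p) / n)),
                "n": n,
            }
        )
    return pd.DataFrame(out, columns=["gender", "bin_low_m", "bin_high_m",
                                      "p_within_5m", "se", "n"])
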