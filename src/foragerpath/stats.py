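"""Summary tables, exact nonparametric tests and effect sizes.

Camp-level land/segregation metrics are aggregated into a per-camp table
with an unweighted cross-camp mean row.  Paired gender contrasts at camp
level use the exact Wilcoxon signed-rank test (sample sizes are far too
small for the normal approximation), and gender effect sizes on continuous
metrics use Cohen's d with a percentile-bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EffectSize:
    cohens_d: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# camp summary (Table-1-shaped)

CAMP_COLUMNS = ["camp_id", "year", "total_km2", "male_km2", "female_km2",
                "ratio", "both_km2", "overlap_pct"]


def camp_summary(camps: pd.DataFrame) -> pd.DataFrame:
    """Append an unweighted cross-camp mean row to a per-camp land table.

    Expects columns ``camp_id, year, total_km2, male_km2, female_km2, ratio,
    both_km2`` (``ratio`` = male/female area; ``overlap_pct`` is recomputed).
    Mean-row conventions: plain column-wise means for areas, the mean of the
    per-camp ratios for ``ratio``, and overlap percent as 100 x mean(both) /
    mean(total) — the ratio of mean areas, not the mean of percentages.
    """
    df = camps.copy()
    df["overlap_pct"] = 100.0 * df["both_km2"] / df["total_km2"]
    mean_row = {
        "camp_id": "Mean",
        "year": np.nan,
        "total_km2": df["total_km2"].mean(),
        "male_km2": df["male_km2"].mean(),
        "female_km2": df["female_km2"].mean(),
        "ratio": df["ratio"].mean(),
        "both_km2": df["both_km2"].mean(),
        "overlap_pct": 100.0 * df["both_km2"].mean() / df["total_km2"].mean(),
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    Returns ``(V, p)`` where V is the sum of the ranks of positive
    differences (|d| ranked with average ranks for ties, zero differences
    dropped).  The p-value is exact, from the full enumeration of the 2^n
    equally likely sign assignments; intended for n <= 25 pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25 pairs")
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    v = float(ranks[d > 0].sum())
    # distribution of V under H0: each rank enters with probability 1/2.
    # Work in doubled-integer rank units so average (.5) ranks stay exact.
    r2 = np.rint(ranks * 2).astype(int)
    total2 = int(r2.sum())
    counts = np.zeros(total2 + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: counts.size - r].copy()
    counts /= counts.sum()
    v2 = int(round(v * 2))
    lo = min(v2, total2 - v2)
    hi = max(v2, total2 - v2)
    p = float(counts[: lo + 1].sum() + counts[hi:].sum())
    return v, min(p, 1.0)


# ---------------------------------------------------------------------------
# Cohen's d


def cohens_d(
    x, y, n_boot: int = 1000, seed: int = 0, ci: float = 0.95
) -> EffectSize:
    """Cohen's d = (mean_x - mean_y) / pooled SD, with a percentile bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per sample")

    def d_of(u, v):
        nu, nv = len(u), len(v)
        sp2 = ((nu - 1) * u.var(ddof=1) + (nv - 1) * v.var(ddof=1)) / (nu + nv - 2)
        if sp2 == 0:
            raise ValueError("zero pooled variance; Cohen's d undefined")
        return (u.mean() - v.mean()) / np.sqrt(sp2)

    d = float(d_of(x, y))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        boots[k] = d_of(rng.choice(x, len(x)), rng.choice(y, len(y)))
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    return EffectSize(cohens_d=d, ci_low=float(lo), ci_high=float(hi))


# ---------------------------------------------------------------------------
# tidy exports

MODEL_TABLE_COLUMNS = [
    "person_id", "camp_id", "gender", "age", "date", "daily_km",
    "daily_m2", "cumulative_m2", "outbound", "inbound", "has_dependent_infant",
]


def export_model_tables(per_day: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """Join per-person-day metrics with person metadata into the model-ready table.

    ``per_day`` needs columns ``person_id, date, daily_km, daily_m2,
    cumulative_m2, outbound, inbound``; metadata supplies gender, age, camp
    and the dependent-infant flag.  The join is inner and validated: every
    exported row carries gender and age.
    """
    merged = per_day.merge(
        persons[["person_id", "camp_id", "gender", "age", "has_dependent_infant"]],
        on="person_id",
        how="inner",
        validate="many_to_one",
    )
    if merged["gender"].isna().any() or merged["age"].isna().any():
        raise ValueError("exported rows must all carry gender and age")
    return merged[MODEL_TABLE_COLUMNS]
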