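# foragerpath

A tested, reusable pipeline for GPS movement-ecology analysis of
central-place foragers — people (or animals) whose daily movement is
anchored to a home base, with out-and-back forays onto the surrounding
landscape. It is aimed at behavioural ecologists and biological
anthropologists who collect person-day GPS tracks in field camps and need
the standard chain from raw fixes to model-ready movement metrics.

## What it computes

For each *person-day* (one individual's track for one local calendar day):

- **Cleaning**: camp-centred equirectangular projection, linear resampling
  to an even 5 s fix interval, removal of spatially errant fixes by maximum
  and modal movement speed, whole-day exclusion of vehicle-contaminated
  travel, in/out-of-camp labelling against a camp boundary polygon, and an
  8-hour minimum recording-span inclusion rule.
- **Day range**: total distance walked per day (km), over all travel.
- **Land visitation** on a 10 m × 10 m raster with per-cell area A:
  daily land visited `N(i,i) × A` and cumulative land explored
  `N(1,i) × A`, where `N(i,j)` counts unique cells intersected from day *i*
  through day *j* (supercover rasterization: every cell whose closed square
  a track segment geometrically intersects).
- **Geographic segregation by gender**: the partition of all visited cells
  into male-only, female-only and both-gender sets; overlap % = both/total.
- **Minimum convex polygons** encompassing 95% of track points (points
  farthest from the centroid excluded first), the conventional home-range
  estimate.
- **Sinuosity** S = L / C, the ratio of path length L to the straight-line
  chord C ≥ 1: outbound and inbound sinuosity of the day's principal
  out-of-camp bout (split at its apex, the point farthest from the camp
  centroid; only bouts reaching ≥ 500 m from camp), and a geographically
  weighted per-grid-cell sinuosity with "high"/"very high" scores against
  the population mean and 99th percentile.
- **Sociality**: a stratified sample of ≤ 100 out-of-camp fixes per
  person-day annotated with the nearest-neighbour distance among all other
  tracked individuals with a fix within ±60 s, an inclusive within-5 m
  indicator, and empirical P(within 5 m) curves by distance from camp.
- **Statistics**: camp-level summary tables with unweighted cross-camp
  means, the exact (enumerated) two-sided Wilcoxon signed-rank test for
  small paired samples, and Cohen's d with bootstrap CIs.

Because field GPS corpora of this kind are typically access-restricted, the
package ships a first-class synthetic generator
(`foragerpath.simulate`): a biased von Mises random walk with camp
anchoring, foraging-party cohesion, adaptive-logging emulation, AR(1) GPS
noise, errant fixes and vehicle contamination — with a ground-truth
manifest so every pipeline stage is testable end to end.

## Worked example

```python
from foragerpath import SimConfig, run_synthetic_study

config = SimConfig(n_persons=4, n_days=3, seed=11)   # 4 men + 4 women, 3 days
sim, result = run_synthetic_study(config)

print(result.per_day.groupby("gender")[["daily_km", "daily_m2", "outbound"]].mean().round(2))
print(f"land ratio male:female = {result.segregation.male_female_ratio:.1f}")
soc = result.sociality.dropna(subset=["nn_dist_m"])
print(soc.groupby("gender").nn_dist_m.median().round(1))
```

prints

```
        daily_km   daily_m2  outbound
gender
female     10.22   88783.33      1.40
male       16.18  143533.33      1.59
land ratio male:female = 4.5
gender
female       2.4
male      1491.3
```

Men (simulated at a 14 km/day range with low heading concentration,
foraging alone) walk farther, visit more raster cells per day, follow more
sinuous outbound routes, and their median distance to the nearest tracked
campmate is three orders of magnitude larger than that of women (simulated
at 8 km/day in cohesive parties of four spaced a few metres apart). The
same contrasts drive the cumulative-exploration, segregation and MCP
outputs in `result`.

The same workflow is available from the shell:

```bash
foragerpath simulate --seed 1 --out sim/
foragerpath report --tracks sim/tracks --camp sim/camp.geojson \
    --persons sim/persons.csv --seed 1 --out report/
```

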