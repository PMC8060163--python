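# Methods

This note documents the models and procedures implemented in
`foragerpath`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
affect results.

## Unit of analysis

The pipeline's atomic unit is the **person-day**: one individual's ordered
GPS fixes for one local calendar day. Local dates are assigned at UTC+3
(East Africa Time; configurable), and recordings running past local
midnight are split at midnight into separate person-days flagged
`midnight_split`. Splitting at midnight is a convention of this package:
all downstream metrics are per-day, and some apportioning rule is needed
for overnight recordings.

## Cleaning pipeline

Order matters and is fixed: **project → resample → vehicle screen → speed
filter → in/out-of-camp labelling**.

- **Projection.** Camp-centred equirectangular: `x = R·Δλ·cos φ₀`,
  `y = R·Δφ` with R = 6 371 008.8 m and (λ₀, φ₀) the camp-boundary
  centroid. For tracks within 30 km of camp the planar distance error
  relative to the sphere is below 0.1% (tested against the haversine);
  beyond 200 km the projection raises. Chosen over a full map projection
  for closed-form invertibility and testability.
- **Resampling.** Linear interpolation onto the even grid t₀, t₀+5 s, …
  ≤ t_end, no extrapolation. 5 s is the native interval of fixed-rate
  loggers; adaptive loggers (dense when moving, sparse at rest) are
  brought onto the same grid. Source gaps > 300 s are bridged but flagged
  `gap_filled`: flagged spans count toward daily distance (the person did
  travel) but are excluded from sinuosity (a straight bridge would bias
  the shape statistic toward 1).
- **Vehicle screen.** A day is dropped entirely when implied speed stays
  above 3.5 m/s for a contiguous run longer than 120 s — the signature of
  a motorcycle/bicycle ride; single errant fixes cannot sustain a run.
  This screen runs *before* spike filtering, because the iterative spike
  filter would otherwise dismantle a sustained fast run point by point and
  silently keep the day.
- **Speed filter.** Stage 1 iteratively removes any fix whose implied
  speeds from *both* neighbours exceed a 20 km/h pedestrian ceiling, to a
  fixed point (endpoints are judged on their single neighbour). Stage 2
  repeats with the limit 10× the modal moving speed — the mode of
  0.1 m/s-binned segment speeds over segments faster than 0.5 m/s. The
  moving-speed restriction is needed because a day with long stationary
  camp hours has a near-zero whole-track mode, which would otherwise
  delete all walking. Removing > 10% of fixes warns; > 50% marks the track
  unusable. Thresholds are configurable; the defaults are conservative
  pedestrian bounds.
- **In/out of camp.** Point-in-polygon against the surveyed camp boundary;
  boundary points count as *in camp*.
- **Inclusion.** Only person-days whose recorded span (t_end − t₀) is at
  least 8 h are analysed; the span criterion (not fix count) makes the
  rule robust to sampling-rate differences.

## Land metrics

The landscape is a square raster (default cell size 10 m, area A = 100 m²)
anchored at the camp centroid. A day's **cell set** is every cell whose
closed square the track intersects — *supercover* rasterization, computed
per segment with a closed-interval Liang–Barsky test over the candidate
cells of the segment's bounding box, so grazing and corner-touching cells
are included and the set is stable under track reversal. Daily land
visited is |cells|·A; cumulative land explored at day *i* is the union of
cell sets over days 1..i times A (non-decreasing by construction).

The raster anchor is a comparability caveat: the grid alignment is not
part of the metric's definition, and absolute areas depend weakly on it.
A regression test jitters the origin uniformly within one cell and checks
that a day-scale track's area coefficient of variation stays below 5%.

**Gender segregation** partitions all cells visited in a camp into
male-only, female-only and both-gender sets (a cell is gender-visited if
at least one person of that gender crossed it on any day). Areas are
reported from exact cell counts, so `male + female − both = total` holds
exactly; camps with tracks from only one gender are excluded rather than
reported with an undefined ratio.

**MCP home ranges** follow the standard convention: discard the
⌈(1−f)·n⌉ points farthest (Euclidean) from the points' centroid with
f = 0.95, then take the convex hull of the rest. Collinear degenerate sets
return area 0 with a warning.

## Sinuosity

Sinuosity is path length ÷ straight-line chord, ≥ 1. Chords shorter than
1 m (loops, dwells) are treated as degenerate and excluded rather than
allowed to blow up the ratio.

**Bout sinuosity.** Bouts are maximal out-of-camp runs bracketed by the
last in-camp fix before departure and the first after return, so chords
are camp-anchored. Bouts never reaching 500 m from the camp centroid are
ignored; among the rest the greatest-path-length bout is the day's
principal bout. It is split at its apex — the *earliest* point of maximum
distance from the camp centroid (a deterministic tie-break that favours a
longer inbound segment) — and each half's path/chord ratio is reported.
Bouts with > 20% gap-filled fixes are skipped.

**Geographically weighted sinuosity** distinguishes turning concentrated
in one place from turning distributed across the landscape. Out-of-camp
travel is segmented by the 10 m grid; a *pass* is a maximal run of
consecutive fixes sharing one cell, extended to the boundary-crossing
points of the entry and exit segments. Pass sinuosity is the in-cell path
length over the entry→exit chord; it reduces to exactly 1 for a straight
crossing. Cells average their passes; a track's cells are then scored
against population statistics computed once over all cells of all tracks
in the run: strictly above the mean = "high", strictly above the 99th
percentile = "very high". The pass/chord construction is this package's
operational definition of "travel crossing through a cell" — it is local,
deterministic, and validated against an independent re-implementation in
the tests — but other readings are possible, and per-cell values are
retained so users can re-score.

## Sociality

From each person-day, up to 100 out-of-camp fixes are drawn uniformly
without replacement (all of them when fewer exist). For each sampled fix,
every other tracked individual contributes their temporally closest fix
within ±60 s (actual measurements, not interpolated positions); the
nearest-neighbour distance is the minimum over contributors, and "within
5 m" is inclusive (≤ 5.0 m). The table carries the covariates needed for
downstream proximity modelling (age, distance from camp, number of
concurrent wearers). The package reports empirical P(within 5 m) by
gender and 1 km distance-from-camp bin with binomial standard errors;
smooth-model fitting (GAMMs) is deliberately out of scope — the tidy
tables are the interface to external model-fitting tools.

## Statistics

- Cross-camp summary rows are **unweighted** column-wise means; the ratio
  column is the mean of per-camp male:female ratios (not the ratio of
  means), and the mean overlap percentage is the ratio of mean areas
  (100·mean(both)/mean(total)), not the mean of percentages. These
  conventions are validated against a published 12-camp reference table in
  the tests.
- The Wilcoxon signed-rank test is **exact**: zero differences dropped,
  average ranks for ties, and the two-sided p-value from the full
  distribution of the 2ⁿ sign assignments (computed by dynamic
  programming in half-rank units). Camp-level paired samples are far too
  small for the normal approximation.
- Cohen's d uses the pooled-SD definition with a seeded percentile
  bootstrap (default 1 000 resamples) for its CI.

## Synthetic forager generator

There is no generative model in the underlying study design; the
generator is this package's stand-in, built so its knobs map one-to-one
onto the contrasts the pipeline measures.

A person-day plan (noiseless, at the 5 s interval): in-camp morning
(piecewise-stationary hearth spots ~40 m around the centre, hops every
~25 min), one foray — outbound walk whose per-step headings are von Mises
around the bearing to a drawn apex with concentration κ, a 20–40 min
foraging dwell at the apex (slow shuffle, Brownian bridge back to the
apex), inbound walk biased toward camp — then in-camp evening. Step
length = speed × interval (1.25 m/s default walking pace). The expected
leg straightness is ρ(κ) = I₁(κ)/I₀(κ), so the apex chord is calibrated
as ρ·(day-range budget)/2, where the budget is the profile's mean day
range minus the expected in-camp and dwell movement (fixed-point
iteration). The manifest records each day's realized noiseless path
length as ground truth.

Defaults define the emulated study conditions: recording span
~N(11.5 h, 1 h) starting ~07:45 local; men 14 km/day, κ = 1.7 (leg
sinuosity ≈ 1/ρ ≈ 1.6), solitary; women 8 km/day, κ = 2.2 (≈ 1.46),
parties of four. Party members share one planned path and differ by a
slowly varying spatial offset (Gaussian knots every ~30 min, linearly
interpolated, stationary SD = `party_spacing`, default 3 m) — members hold
a near-constant position in the walking line, so cohesion is controlled
without inflating individual path lengths. Day-to-day variation is a
lognormal factor (CV 20%) on the apex chord.

Measurement error is AR(1) per coordinate (SD 1.5 m, correlation time
600 s): consumer receivers smooth internally, so their error drifts
slowly rather than jumping per fix. This matters quantitatively — white
noise of realistic amplitude at 5 s sampling would add tens of kilometres
of spurious distance per day; the AR(1) model adds the gentle inflation
(~1–2 km/day) actually seen in field tracks, which is why measured day
ranges sit slightly above, and the measured male:female ratio slightly
below, the configured generative values. Errant fixes (uniform in a 5 km
disc, default rate 2×10⁻⁴/fix) exercise the speed filter; an optional
(speed, duration) vehicle segment exercises the vehicle screen; optional
adaptive-logging emulation thins fixes to one per 15 s below 0.2 m/s.

Per-person-day RNG substreams are derived by stable hashing of
(seed, party id or person id, date), so any single track is reproducible
regardless of generation order.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: terrain, vegetation and trail networks; hunting
pursuit dynamics and multi-stop gathering circuits; inter-party encounter
structure; heteroscedastic GPS error (canopy, canyon multipath); device
dropout mid-day. Tests against the generator validate the *pipeline's
measurements against known ground truth*, not any empirical claim about
real foragers.

## Problem sizes and determinism

The default synthetic study used by the test suite and the acceptance
script is 10 persons per gender × 5 days (≈ 830 000 fixes), chosen as the
smallest run in which all gendered contrasts are stable across seeds; it
completes in well under a minute on one core. Identical configuration and
seed give byte-identical outputs throughout the pipeline.

## Known limitations

- Absolute raster areas depend weakly on grid anchoring (see above) and
  on the supercover convention (a conservative, superset-style
  rasterization; midpoint rasterizers report smaller areas).
- The equirectangular projection is unsuitable beyond ~200 km or at high
  latitudes; camps are assumed tropical/temperate and local.
- Gap-filled spans are included in distance but excluded from sinuosity;
  if real devices drop fixes preferentially during fast sinuous travel,
  both conventions bias shape statistics in ways no post hoc rule can fix.
- The exact Wilcoxon implementation enumerates up to n = 25 pairs; larger
  samples should use a large-sample method instead.
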