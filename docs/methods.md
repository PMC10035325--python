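# Methods

## Unit of analysis and study periods

The unit of analysis is the *block-group-period*: one census-style polygon
observed in one inclusive window of calendar years. The canonical windows
are 2005–2009, 2010–2014, and 2015–2019, chosen to align with ACS 5-year
demographic products; any non-overlapping windows are accepted. A date `d`
is "within" a period iff `start_year <= year(d) <= end_year` — calendar-year
membership, because the demographic denominators are calendar-year
aggregates.

## Well life-cycle model

Each well carries a spud date (start of drilling, opening preproduction), a
completion date (end of preproduction), first/last production dates, annual
production volumes in BOE, and possibly an abandonment date. Stage
predicates, evaluated independently per period:

* **new** — the preproduction interval `[spud, completion]` overlaps the
  period. A missing completion leaves the interval open-ended on the right
  (the well may still be in preproduction). A missing spud with a present
  completion collapses the interval to the completion date alone: completion
  marks the end of preproduction, and without the left endpoint the
  single-point interval is the conservative choice (logged per well). With
  neither date a well is never new.
* **active** — cumulative BOE over the period's years is strictly > 0.
* **retired** — the postproduction start falls in the period, where
  postproduction starts at the reported abandonment date, or 8 years after
  the last production date when no abandonment is reported (the long-term
  idle rule; the statute is phrased in years, so the shift is
  calendar-exact, same month and day, with Feb 29 mapping to Mar 1).
  Retirement is evaluated per period, not once over the whole study span.
  Each assignment records whether retirement came from a reported
  abandonment (`abandonment`) or the idle rule (`idle_rule`), so the
  plugged-versus-idle split among retirements is recoverable.
* **plugged** (cross-sectional, reference year 2019 by default) — status
  marker says plugged and the abandonment date, if any, is not after the
  reference year. Plugged wells with no dates at all are assumed plugged
  before the reference year and included; plugged-status wells abandoned
  *after* the reference year are excluded, keeping the cross-section fixed.

Stages are not exclusive: a well spudded in one year of a period and
producing in the next is both new and active there.

Input hygiene: negative annual volumes (ledger adjustments in production
data) are clamped to 0 with a warning, since the activity rule is defined
on produced volume; spud-after-completion is a warning on ingested data,
never fatal; year-only dates map to July 1 (midpoint, minimizing bias) with
a warning.

## Exposure assessment

All geometry is planar, in projected metres; degree-valued coordinates are
rejected outright (a 1 km buffer in degrees is meaningless) and
reprojection is a documented pre-step outside the package. Input polygons
that fail validity (self-intersections from digitizing artifacts) are
repaired by zero-width buffering with a warning.

**Areal apportionment.** Per stage and period, 1 km discs (default; any
radius > 0) around every staged well are dissolved into a single region
before intersection, so overlapping per-well buffers never double-count
residents. The exposed fraction of a block group is
`area(geometry ∩ buffer) / area(geometry)`, clipped to [0, 1], and every
demographic count is multiplied by it *unrounded* — areal weights are
continuous, and early rounding would break the invariant that the seven
race/ethnicity exposures sum exactly to the exposed total population.
Rounding happens only in report tables.

Discs are approximated by regular 64-segment polygons (shapely
`quad_segs=16`), making runs bit-reproducible and giving area tolerances a
concrete meaning: a 64-gon underestimates disc area by ~0.16%, and
intersection results are exactly invariant under translations and under
rotations in the polygon's symmetry group, but differ by up to ~1e-5
relative under arbitrary rotations of the whole scene. Tests assert
invariance accordingly (exact at 90°, 1e-4 at a generic angle).

**Centroid intensity.** The centroid is the area-weighted geometric
centroid, even when it falls outside a concave polygon (flagged in logs);
the distance predicate is boundary-inclusive (`<= radius`), a deterministic
choice on a measure-zero tie set. Active-well intensity sums each counted
well's cumulative BOE over the period window only, not its whole history.

## Disparity statistics

`RR = (group_exposed/group_total) / (pop_exposed/pop_total)`. Zero
denominators make the ratio *undefined*, emitted as an explicit marker
(`NA` in CSV), never 0 and never silently dropped — dropping undefined
cells would bias group comparisons. Internal values are unrounded; report
tables round RR to 2 decimals and percentages to 1.

Scopes restrict both numerator sums and denominator totals: statewide uses
every block group, a county scope only that county's. Socioeconomic
indicators are ratios over their own universes (people below twice the
poverty line over the poverty universe, adults without 12 years of
education over the education universe, renter over total households,
linguistically isolated over total adults, nonvoters over eligible voters);
the voter pair is absent from the earliest period and skipped there.

**Quintiles.** Among block groups with positive active-well centroid BOE,
equal-frequency quintiles (1 = least exposed) are assigned by rank; tied
values all take the quintile of the smallest rank in the tie group — a
deterministic rule preferred over random tie-breaking. Quintile RRs use
quintile-restricted numerators over statewide denominators, which
guarantees the total-population RR is exactly 1 in every occupied quintile
(any defensible reading of the stratified ratio must satisfy this);
unoccupied quintiles yield records with undefined RR.

**Panel change.** For two periods sharing a block-group frame, block groups
are categorized by the sign of the change in a metric (new-well centroid
count, or cumulative centroid BOE); "no change" means exact equality for
integer counts and |Δ| < 1e-6 BOE for volumes, so floating-point
accumulation cannot create spurious categories. Demographic sums within
categories use the later period's counts (configurable); the later period
matches the contemporaneous framing of the change maps this analysis
feeds.

No confidence intervals or hypothesis tests are attached to the ratios:
the statistic is a descriptive point ratio over full enumerated
denominators, not a sample estimate.

## Synthetic landscapes

The generator emulates the *structure* the analysis assumes, not any real
geography. Block groups are an `nx × ny` grid of squares (default 8 × 8 at
2 km — intersections against axis-aligned cells are exactly computable for
oracles); populations default to the 600–3,000 range typical of census
block groups (uniform draw; fixed at 1,500 in deterministic mode). The
race/ethnicity partition uses California-like base shares; the planted
disparity multiplies the target group's share by
`1 + (m − 1)·exp(−d/L)` with `d` the distance to the nearest well cluster
(default length scale L = 2 km), renormalizing the other groups, so `m = 1`
plants nothing. Socioeconomic universes are fixed fractions of population
with spatially uniform rates, so their expected RRs are 1.

Wells are clustered (Poisson counts, at least one per cluster, Gaussian
dispersion); each draws a coherent life history — spud year, preproduction
of 30–240 days, a production lifetime, annual volumes that are log-normal
(default median 1,000 BOE, σ = 2.5 on the log scale, emulating the extreme
right skew of real production registers), abandonment with configurable
probability 1–3 years after last production. A configurable fraction
(default 44.3%) of plugged wells then has its closing dates blanked,
emulating legacy wells with no reported last-production or abandonment
dates; ordered-date invariants hold before blanking. All randomness flows
through substreams of one seeded generator (wells, demographics, clusters
and tribal polygons never share draws), so identical seeds give
byte-identical outputs.

**Closed-form oracle.** In deterministic-demographics mode with clusters
snapped to distinct cell centres, zero dispersion, and buffer radius at
most half the cell size, each cluster cell's exposed fraction is exactly
(64-gon area)/(cell area) and every other cell's is 0; `expected_rr`
computes the statewide RR per group analytically from that and the planted
shares, independent of the exposure and aggregation code it checks.
Outside this configuration (stochastic mode, free-floating clusters) it
refuses rather than approximate. End-to-end recovery agrees to better than
1e-6; null landscapes over 50 seeds keep each group's mean RR within 3
standard errors of 1.

What passing these tests shows — and does not. The synthetic tessellation
has convex, equal-area cells, uniform within-cell density, and a
monotone radial disparity; real block groups are irregular, populations
cluster within them (no dasymetric refinement is attempted), boundaries
change at each decennial census, and real well registries carry reporting
errors beyond clamped negatives and blanked dates. Passing therefore
validates the estimator machinery, not the field accuracy of any real-data
result.

## Problem sizes in the standard test run

The suite's heavier checks use the sizes its oracles call for: 50
randomized landscapes with 200,000-point Monte-Carlo sampling for the
areal-fraction oracle, 50 seeded replicates for null calibration, 200
randomized wells for the life-cycle oracle, and 5–6 cell grids elsewhere;
the full run takes a few seconds on one CPU.

## Known limitations

* No distance-decay weighting, multi-ring buffers, or dasymetric
  population refinement; exposure is a uniform-density area share at a
  single radius.
* No well re-activation model: once the idle rule marks postproduction,
  later production does not rescind it (the classification is per period,
  so a well producing again simply counts active in that period too).
* County assignment is an attribute on block groups, not a spatial join.
* GeoJSON is the only geometry interchange format; shapefile readers and
  CRS transformation belong to upstream tooling.
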