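# Methods

This note documents the models, conventions and numerical choices
behind `cpforage`, and what the synthetic-data experiments do and do
not demonstrate about real tracking data.

## Geodesy

All distances are great-circle (haversine) on a sphere of radius
6371.0088 km (IUGG mean); ellipsoidal corrections (< 0.5%) are far
below GPS accuracy at foraging-trip scales and are out of scope.
Bearings are *initial* great-circle bearings in [0, 360). At the
≤ 520 km trip scale the initial bearing differs negligibly from the
constant bearing, so sector classification is insensitive to the
choice. Longitudes are normalised to [-180, 180) at construction.
Requesting the bearing between coincident points raises a dedicated
error rather than returning 0, which would silently bias circular
statistics.

## Trip segmentation and cleaning

A fix is at-colony when its displacement from the colony centre is
**≤** the colony radius (default 400 m — above the few-hundred-metre
wander GPS tags show on nesting birds). The inclusive boundary keeps
classification stable under float noise. Trips are maximal contiguous
at-sea runs within a deployment; colony fixes belong to no trip; runs
touching the record boundary are kept and flagged
(`starts_at_sea`/`ends_at_sea`) rather than repaired, because a
truncated record is information (birds often depart the moment a tag
is attached). A single stray at-colony fix splits a run: no smoothing
rule is applied, and none is needed for regularly-sampled data. Trips
are never split on time gaps; sampling in the emulated study design is
regular (10–20 min).

Cleaning removes, in order, (1) trips with fewer than 11 fixes, then
(2) trips with sinuosity S > 0.5. Ordering first makes every removal
uniquely attributable in the manifest. S exactly 0.5 is kept: an
ideal straight out-and-back trip sits on the boundary. S above 0.5 can
only arise when part of the loop is missing (e.g. an at-sea start), so
it flags truncation, not behaviour.

## Trip metrics

Total distance sums consecutive at-sea fix-to-fix legs only — the
colony coordinate is *not* prepended or appended. This is deliberate:
with colony anchoring a truncated trip would be silently "repaired"
and the S > 0.5 truncation signal destroyed. Duration is first to last
at-sea fix; the alternative (colony departure to return) differs by at
most one sampling interval. The max-displacement coordinate is the
*first* fix attaining the maximum (deterministic, order-stable).
Because the at-sea record starts and ends ~400 m from the colony, even
a perfectly straight trip has S marginally above 0.5 by ~r/D (colony
radius over trip scale); at typical trip scales this is < 0.01.

Region boundaries (east 355–130°, southwest 130–260°, northwest
260–355°) form a half-open partition, each boundary belonging to the
sector it opens. Depth bands are land (< 0 m), shelf [0, 200), shelf
break [200, 1000], pelagic (> 1000 m); the paper-style statement
"deeper than 1000 m is pelagic" fixes the 1000 m boundary in the
shelf-break band, and the 200 m choice mirrors it. Both are
configurable. A trip's habitat class is the deepest band over its
fixes (pelagic > shelf break > neritic). Bathymetry lookup is
nearest-cell without interpolation: class boundaries are hundreds of
metres of depth while one cell's quantisation error is tens of metres.
The grid format is the ESRI ASCII grid (plain text); rasters storing
elevation rather than depth are negated at load via a flag.

## Individual consistency

Trips are summarised by their max-displacement coordinate, and
similarity between two trips is the great-circle distance X between
those coordinates. Three pair sets are built: **reference** (default:
one seeded-random trip per individual, then all C(n, 2) unordered
cross-individual pairs), **within-season** (all pairs within a
deployment) and **between-season** (one seeded-random trip per
individual per season, all cross-season pairs per individual). The
one-trip-per-individual reference default reproduces the printed
reference count of a 96-bird study, C(96, 2) = 4560, which an
all-trips set cannot; an `all_trips` mode is available. Distances are
binned (default 50 km bins to 1100 km, ~twice the maximum plausible
pair separation; the final bin absorbs overflow) and compared with a
two-sample (2×k contingency) G-test. Expected counts come from the
margins, zero observed cells contribute 0, and bins are pooled from
the right tail inward until every expected count is ≥ 5 (standard
small-expected-count practice, recorded in the result); at least two
bins are always retained. A goodness-of-fit mode treating the
reference as fixed proportions exists behind a flag, but the default
treats the reference as a sample, which it is.

**Known limitation — dependence of pair sets.** The G-test's
chi-squared reference assumes the binned counts are multinomial, i.e.
that pair distances are independent draws. Pairwise-distance sets are
U-statistics: all pairs among m points share endpoints, so the
histogram of C(m, 2) reference distances carries roughly the
information of O(m) independent draws, and the within-individual
triples overlap likewise. Under a true null (no fidelity), the test
therefore rejects more often than the nominal α — replicated
simulations in this package measure ~0.16 at α = 0.05 for a 40-bird,
3-trip design. The test is kept in its standard form because the
p-value is defined by the chi-squared tail; the practical consequence
is that marginal p-values just below α should not be over-read,
whereas effects at realistic fidelity strengths yield p-values tens of
orders of magnitude below α (the demo reports p ≈ 1e-54) and are
unaffected. The acceptance suite documents this as an expected
failure of the nominal-calibration check.

## Covariate statistics

Welch's unequal-variance t-test is the default two-sample test (the
pooled-variance form is available by flag); degenerate zero-variance
inputs return t = 0, p = 1. Age effects use ordinary least squares
with the overall F = t²_slope on (1, n − 2) df and a 95%
mean-confidence band for plotting. Year effects use classical one-way
ANOVA. No multiple-testing correction is applied: raw p-values are
reported, matching common practice for these descriptive covariate
screens — readers comparing many metrics should adjust accordingly.

Bearings are circular, so group comparisons use a von Mises
likelihood-ratio test with common concentration κ: the null fits one
mean direction, the alternative one per group, κ re-estimated under
each model from the resultant lengths via the standard three-piece
closed-form inverse of A1(κ) = I1(κ)/I0(κ) (pieces at R̄ = 0.53 and
0.85). The statistic 2(ℓ₁ − ℓ₀) is referred to χ²(g − 1), clamped at
zero if numerically negative; κ̂ is capped (with a warning) as R̄ → 1.
The LRT form is chosen over Watson–Williams because it generalises
cleanly to g groups and reports a chi-squared statistic. Replicated
null simulations (7 groups of 26, κ = 2, mimicking a seven-season
design) put its type-I error at ~0.05–0.06 — nominal within binomial
error at these sample sizes, though mildly anticonservative for much
smaller groups.

Sequential sinuosity differences ΔS are computed between consecutive
time-ordered trips within a deployment and between the first trips of
an individual's successive tracked seasons. The accompanying
two-sided one-sample t-test of mean ΔS = 0 is an explicit addition:
the underlying descriptive comparison is usually presented
graphically, and the test makes "no directness trend" falsifiable.

## Synthetic data

The generator emulates the statistical structure of a multi-season
incubation-stage tracking study, not albatross flight physics (no
wind, soaring, currents, or tag-failure model beyond optional start
truncation). Defaults and rationale:

- **Colony** at (−40.3780953, 144.6557384), radius 400 m; colony
  residencies jitter fixes uniformly within 350 m (observed nesting
  wander), plus 10 m GPS noise on every fix.
- **Roster**: 96 individuals over seven seasons (2013–2019), one
  deployment per tracked season, 1–6 trips per deployment with mean
  ≈ 2.2, re-tracking probability 0.25 per extra season (giving ~20%
  multi-season birds). Sampling every 10 min, 20 min in the 2018
  late-winter season.
- **Targets**: each individual has a preferred site drawn from a
  population pool — bearings from a two-component von Mises mixture
  (87% around 286°, κ = 2; 13% around 60°, κ = 1, giving the
  west-dominant structure), distances lognormal (median 150 km,
  σ_log = 0.6) clipped to 9–520 km, the printed displacement range.
  Per-trip targets displace the preferred site isotropically in the
  local tangent plane with sd `fidelity_sd_km` (default 20 km);
  setting the knob to 0 draws every target from the pool,
  disabling individual preference. Tangent-plane displacement avoids
  the lat/lon anisotropy a naive degree-space jitter would have at
  40° S. Within-individual pair distances are then Rayleigh with
  scale σ√2, mean σ√π — a closed form the tests check.
- **Tracks**: correlated random walk toward the target (heading = 
  bearing-to-goal + von Mises noise, κ = 20; `None` means straight),
  cruise speed N(30, 5) km/h floored at 5, an area-restricted-search
  dwell near the target (6 km/h, ~60° heading wander, re-centred
  beyond 5 km) of 12 h by default, then a return leg. Legs start and
  end on a 0.45 km standoff ring: far enough outside the 400 m colony
  radius that GPS jitter cannot flip the boundary fixes, close enough
  that a straight trip's S lands within 0.01 of 0.5. With these
  defaults trip durations span hours to ~2 weeks and path lengths
  reach a few thousand km — the study-scale ranges; they are design
  targets, not biological claims.
- **Planned sinuosity**: an optional schedule sizes the dwell so trip
  k of a deployment realises S ≈ first + k·drift (clipped to
  [0.05, 0.5]), enabling exact recovery experiments on the
  learning-signal statistics.
- **Determinism**: one seed; per-individual substreams are seeded from
  (seed, individual index), so adding an individual never perturbs
  existing tracks, and identical configs give byte-identical output.

`simulate_trip_summaries` is a fast path that draws the same roster
and per-trip targets but skips track integration, returning targets as
max-displacement coordinates. It is used for replication-heavy
calibration experiments on the pairwise-distance statistics, where the
km-scale difference between a track's true max-displacement coordinate
and its target is negligible against 20–300 km pair distances. It is
*not* a substitute for track-level tests: segmentation, cleaning,
metric and drift experiments all run on full tracks.

Synthetic bathymetry is an analytic, radially monotone depth field
(shelf rising 20→200 m out to a 150 km shelf edge, a 60 km break band
200→1000 m, then an 8 m/km pelagic slope capped at 5500 m) sampled at
cell centres, so grid lookups can be checked against the closed form.

What passing these tests shows: the pipeline's bookkeeping,
geometry, and statistics are correct under a data-generating process
with the study's *structure*. What they do not show: robustness to
irregular sampling, location error beyond isotropic jitter,
behaviour-dependent gaps, or movement unlike a biased random walk —
real-data caveats that sit outside this generator.

## Problem sizes

The test suite simulates at reduced scale (populations of 6–96
individuals, single- or two-season rosters) and the replicated
calibration experiments use 100–500 replicates at the summary level
and 6–20 full-track populations; these sizes give binomial/KS checks
adequate resolution while keeping the whole suite under a minute of
compute. The acceptance script mirrors them.
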