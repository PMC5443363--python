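# Methods

## Scoring model

Each subject is scored against a sex-specific LMS growth reference: a grid
of age knots (months) carrying the Box-Cox power *L*, median *M* (kg/m²)
and coefficient of variation *S* of the BMI distribution at that age. The
z-score of a BMI value *X* is `((X/M)^L − 1)/(L·S)` (log form for L = 0);
the percentile is the standard-normal CDF of that z, and the inverse map
`M·(1 + L·S·z_p)^(1/L)` yields the BMI at any percentile, including the
P95 needed for `BMI_95 = 100·BMI/P95`. The assumptions are the usual LMS
ones: at each sex and age, a Box-Cox power transform of BMI is normal, and
the three parameters vary smoothly with age.

Numerical choices: the two LMS branches are evaluated with
`expm1`/`log1p`, which makes the L ≠ 0 branch converge exactly to the log
branch as L → 0 and keeps the transform strictly monotone even for
pathologically small |L| (below 1e−150 the log branch is used outright —
the difference is O(L)). Z-scores are never truncated: the far upper tail
is precisely the severe-obesity range this package exists to show. The
percentile→BMI inverse raises a domain error when `1 + L·S·z ≤ 0`, where
the Box-Cox distribution is undefined. Round-tripping BMI → z →
percentile → BMI is identity to 1e−9 relative tolerance for |z| ≤ 5; past
that the double-precision normal CDF/quantile pair cannot carry the
information, and the pipeline consequently clamps a float-saturated
percentile (Φ(z) rounding to exactly 0 or 1) into the open interval before
classification only — reported values are untouched.

## Reference tables and interpolation

Reference tables are validated on load: both sexes present, ages strictly
increasing within sex in [24, 240.5] months, covering 24–240, M and S
positive; offending rows are named in the error. Between knots, L, M and S
are each interpolated linearly in age — simple, monotone, exact at knots
and continuous. Subject ages are converted as `age_months = Age_y × 12`
exactly; calendar arithmetic from dates of birth is the caller's
preprocessing. Supported subject ages are [2, 20) years; out-of-range rows
are flagged and left unscored rather than aborting the batch or
extrapolating the reference.

## Classification

Six mutually exclusive categories; severity is evaluated from the top so
the OR-shaped severe-obesity criteria cannot overlap: class 3 (BMI_95 ≥
140 or BMI ≥ 40), class 2 (BMI_95 ≥ 120 or BMI ≥ 35), obese class 1
(percentile ≥ 95), overweight (≥ 85), healthy (≥ 5), underweight
otherwise. All lower bounds are inclusive, upper bounds exclusive. A
subject with BMI 36 but BMI_95 of 118 is class 2 through the absolute-BMI
arm even though the percent arm alone would say class 1; most-severe-first
is the only evaluation order consistent with mutually exclusive
categories. The classifier treats percentile and BMI_95 as independent
inputs and does not enforce consistency between them. Prevalence summaries
report per-category counts/proportions plus the two standard aggregates:
obesity (classes 1–3) and severe obesity (classes 2–3).

## Cohort I/O

Input files (CSV/.xlsx/.xls) need `ID, Sex, Age_y` plus either
`Height_cm`+`Weight_kg` or `BMI`; headers match case-insensitively and sex
accepts F/M/female/male in any case. Height and weight are preferred for
computing BMI; a supplied BMI is a fallback, and a supplied BMI
disagreeing with the computed one by more than 0.1 kg/m² is flagged
without altering the result. English units are converted with
`cm = in × 2.54` and `kg = lb / 2.20462`. Whole-number ages are flagged as
a misclassification risk but still scored. Replicated IDs mark a data set
longitudinal; a replicated ID carrying two different sexes makes those
rows unscorable (the reference is sex-specific) and they are flagged. The
results CSV (`BMI_Results.csv`) preserves the input columns, appends
`BMI_kgm2, BMI_pct, BMI_z, BMI_95, Weight_status` and a QC_flags column;
BMI, percentile and BMI_95 are written to 2 decimals, z to 4, with full
precision kept in memory.

## Charts

Charts put age (years, 2–20, integer ticks) on x and BMI on y with a
default range of 10–60 kg/m²: the ceiling accommodates severe obesity,
the floor sits below the P5 curve's minimum. Default curves are the 5th,
50th, 85th and 95th percentiles plus 120% and 140% of P95 (the class-2 and
class-3 cut points); any extra percentiles can be requested, and curves
across increasing percentiles are pointwise ordered by construction.
Rendering is two-stage: results are first assembled into a `Scene`
(curve arrays, point coordinates, per-child polylines) that tests assert
on directly, then drawn by matplotlib to EPS or PDF. Points are plotted at
their exact (age, BMI) with no jitter; points above the y ceiling are
clipped to it with a logged count, never dropped silently. Output files
are byte-reproducible (embedded timestamps and file-path titles are
normalized). Default file names follow the
`BMI_Graph_{females,males}[_long].{eps,pdf}` family; no generating-tool
suffix is appended. Longitudinal charts cycle a color per child by
default (configurable to monochrome) — with a few dozen trajectories,
distinguishability beats uniformity.

## Synthetic reference and cohorts

`make_reference()` produces a smooth, deterministic two-sex LMS table on a
24–240.5 month half-month grid: M rises 16 → 27 kg/m² (smoothstep, males
offset +0.3 by age 20), S arches from 0.08 up to ~0.14 mid-childhood and
back, L declines linearly 1 → −2. The S schedule is deliberately not
maximal at the oldest ages: were S ≈ 0.16 at age 20 with M ≈ 27, the
implied P95 would exceed 35 kg/m² and the obese-class-1 band
(P95 ≤ BMI < min(1.2·P95, 35)) would be empty there — real growth
references keep P95 near 31–33 kg/m², and so does this one (verified by a
test).

`make_cohort(n, ...)` draws ages uniformly in [2, 20), assigns each
subject an intended category (uniform over the six by default), and
inverts the reference to place the BMI strictly inside that category's
region with margins of 0.5 percentile points, 0.5 percent-of-P95 and
0.1 kg/m² — so a correct pipeline must recover the intended category for
100% of rows, while boundary behavior is tested separately with
hand-placed values. Where the percent-of-P95 arm for class 2 is infeasible
(1.2·P95 ≥ 40), the generator falls back to the absolute-BMI arm and
records which arm it used. Height comes from a crude sex-specific linear
height-for-age model with mild noise and weight is back-solved from the
target BMI; the controlled quantity is BMI. Longitudinal mode gives each
child 2–5 visits spanning at most four years with the category held
fixed. Identical seeds reproduce byte-identical files.

What the generator does *not* emulate: realistic growth-trajectory
autocorrelation, survey sampling design, measurement error in
height/weight, or secular trends. Passing the recovery tests therefore
demonstrates internal consistency of scoring + classification against a
known ground truth — not agreement with any national reference, which
users must supply themselves.

## Problem sizes and defaults

Tests and the acceptance script use a 600-subject uniform-mix cohort for
recovery, 100 000 random triples plus an ε-boundary grid for the
classifier partition sweep, a 4000-subject cross-sectional and
30-trajectory longitudinal render for the capacity checks, and 2000 draws
for the round-trip error — comfortably converged sizes for what each
check measures. Chart defaults: y-max 60 kg/m², ages 2–20, half-month
curve grid.

## Known limitations

- No reference values ship with the package; results are only as good as
  the supplied LMS table.
- Linear interpolation of L, M, S is a pragmatic choice; references
  published on fine grids make the difference negligible, coarse custom
  grids may not.
- Percentiles indistinguishable from 0 or 100 in double precision are
  reported as such; the classifier handles them, but downstream consumers
  rounding to two decimals will see 0.00/100.00.
- Only EPS and PDF outputs; no raster or interactive charts.
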