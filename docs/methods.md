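# Methods

## Scope and design

`smbgloop` implements a weekly, SMBG-driven treat-to-target titration loop
for twice-daily premixed insulin, the safety and outcome analytics of a
24-week pre-post intervention, and a virtual-patient simulator able to run
the complete closed loop. The published description of such interventions
fixes the target band (4–8 mmol/L), the weekly review cadence with
out-of-cycle review on hypoglycemia, the 15–20% step ceiling, and the
physician accept/decline gate, but leaves the operational rule constants to
a proprietary appendix. The constants chosen here are therefore declared
approximations, exposed in `TitrationConfig`, and documented below.

## The titration rules and their open choices

**"Consistently" outside the band.** Defined as: at least 4/7 of the
slot's deduplicated weekly readings beyond the band edge *and* the slot
median beyond it. The conjunction makes the rule robust to a single
outlier strip in a 7-day window; with fewer than 4 readings in a slot the
week is *insufficient* and no change is made.

**Reading → dose governance.** The evening premix acts overnight and sets
the next fasting (prebreakfast) value; the morning premix carries through
the day to the predinner value. Prebreakfast readings therefore govern the
evening dose and predinner readings the morning dose. This is the standard
premixed-insulin convention and is fixed, not configurable.

**Step tiers.** "Up to 15% to 20%" is read as two tiers applied per dose
(not to the total daily dose): 15% when the slot median is within
2 mmol/L of the violated band edge, 20% beyond that. Steps are rounded
half-away-from-zero to whole pen units with a minimum effected change of
1 unit, and are hard-capped at ⌈20% × dose⌉.

**Hypoglycemia precedence.** Any level-2 reading (< 3.0 mmol/L), or at
least two level-1 readings (3.0–3.9 mmol/L), in a slot's week vetoes an
increment of its governing dose and forces a decrement (20% when level 2
was seen, else 15%) — regardless of what the rest of the week looks like
and even when the slot has fewer than the minimum readings. A reading
below 3.0 mmol/L additionally fires an *urgent* out-of-cycle 20%
decrement, at most once per slot per review window. These thresholds err
on the conservative side; the urgent threshold coincides with the level-2
boundary.

**Dose safety rails.** Doses floor at zero (a mandated decrement of a
zero dose is reported as `capped`), and the recommended total daily dose
may not exceed 1.5 units/kg (configurable). When the cap binds, increments
are truncated in a fixed order (morning first). A fixed truncation order —
unlike "largest increment first" — keeps the recommendation weakly
monotone in each slot's readings even at the cap, a property the test
suite asserts.

**Physician gate.** Every recommendation is pending until accepted or
declined, exactly once; the simulator's gate accepts with configurable
probability (default 1.0, since decline statistics are not published).

## Hypoglycemia levels and episodes

Levels follow the consensus definitions: level 1 = 3.0–3.9 mmol/L
(inclusive at both ends), level 2 = < 3.0 mmol/L, level 3 = severe
(requiring external assistance) regardless of the concurrent glucose.
Episode extraction merges qualifying readings closer than 60 minutes into
one clinical event recorded at the lowest glucose — repeated confirmatory
strips are one episode, not several. The debounce gap is configurable down
to zero, where episode count equals qualifying-strip count; merging can
only reduce the count. Each episode is assigned to the first or second
half of the study by whole days (days 0–83 vs 84–167 in a 24-week study).

## Outcome analytics

Adherence is 100 × completed/prescribed readings (twice daily: 168 per
12-week period per participant), reported to 1 decimal; per-participant
incidence is episodes/cohort-size to 2 decimals — both at the display
precision clinical reports use. Timepoint summaries are complete-case per
cell with the per-cell n reported and missing participants flagged. Only
descriptive change scores between timepoint means are computed;
significance testing is deliberately out of scope.

Unit conversions: NGSP→IFCC HbA1c via the master equation
IFCC = (NGSP% − 2.15) × 10.929 (domain NGSP% > 2.15 — the intercept
itself is rejected as non-physiological), and estimated average glucose
via the ADAG relation eAG [mmol/L] = 1.59 × HbA1c% − 2.59, with an exact
inverse. A caution when comparing against published tables: mmol/mol
values printed in reports are typically converted from *unrounded* means,
so converting the rounded percentage can differ in the last digit (8.6% →
70.5 by the master equation, against a printed 70.4 derived from the
unrounded mean). `analysis/04_reported_arithmetic.py` tabulates exactly
this.

## The virtual patient

The generative model is the simplest one that closes the loop and leaves
every behaviour analytically checkable:

    reading(slot, day) = setpoint_slot − S · d_gov/W + ε,   ε ~ N(0, σ²)

with `S` the insulin sensitivity (mmol/L drop per unit/kg of governing
dose), `d_gov` the governing dose in units, `W` body weight in kg, and σ
the within-day SD. Each prescribed reading is performed with probability
`adherence_prob`; readings are floored at 0.5 mmol/L. HbA1c is tracked as
an exponentially weighted moving average of the daily mean *latent*
glucose with a 35-day time constant — roughly the red-cell-turnover
kinetics that make HbA1c a 2–3-month integral — mapped through the ADAG
relation; laboratory draws at weeks 0/12/24 add N(0, 0.1%) HbA1c noise,
and FPG is the fasting latent value plus N(0, 0.3 mmol/L) lab noise.

Cohort generation rejection-samples the enrollment criteria (HbA1c
7.5–9.9%, realized TDD < 1 unit/kg after whole-unit rounding, BMI ≤ 40)
from Gaussian moments defaulting to the study population (HbA1c 8.6 (0.7)%,
TDD 0.73 (0.31) units/kg/day, BMI 29.0 (3.6) kg/m²). Height (N(1.62,
0.08) m) supplies body weight via BMI, reproducing the implied ≈78 kg mean;
the initial TDD is split 60/40 between morning and evening premix.
Sensitivity is N(10, 2.5) mmol/L per unit/kg truncated at 2 — large enough
that the band is reachable under the 1.5 units/kg cap for a typical
patient; within-day SD is N(1.4, 0.3) mmol/L, producing a realistic
Gaussian-tail hypoglycemia rate that rises as control tightens (there is
no separate hypoglycemia event process); adherence_prob is Uniform(0.94,
1.0), matching the high completion fractions such interventions report.
Slot setpoints are initialized so that the *mean* latent glucose under the
enrollment regimen equals the eAG implied by baseline HbA1c, with a
mean-preserving diurnal offset (fasting 2.4 mmol/L below the daily mean,
predinner the same above) that reproduces the typical gap between fasting
plasma glucose and eAG at enrollment.

One root seed drives everything; it is split into per-patient substreams
(`numpy` `SeedSequence.spawn`), so per-patient trajectories are independent
of cohort ordering and a run is byte-identical under the same config.

### What the simulator does and does not emulate

It emulates: twice-daily slot-labelled SMBG with missed readings,
dose-responsive glucose with realistic dispersion, Gaussian-tail
hypoglycemia that increases under tighter control, HbA1c lag, lab noise,
and the complete weekly titration/approval loop. It does not emulate
meals, exercise, insulin pharmacokinetics beyond the static linear
dose-response, behaviour change, dropout, or any non-linearity of the
glucose–insulin system. Consequently the virtual cohort improves *only*
through dose escalation and converges near the band edge: its simulated
HbA1c change (≈ −2%) and dose change (≈ +0.7 units/kg/day) are a property
of the linear model, not a reproduction of clinical effect sizes, where
most of the improvement is attributed to dose redistribution and
behaviour change rather than dose quantity. An optional
`setpoint_drift_per_week` parameter can emulate behavioural improvement,
but no claim is made that it reproduces any trial's effect size. Passing
tests therefore certify the *rules engine and analytics*, and the
simulator's internal consistency — not predictive validity on real
patients.

## Numerical choices and degenerate inputs

- Rounding: half-away-from-zero for dose steps (pen units); display
  rounding only at the reporting layer.
- The consistency threshold is compared with a 1e-12 slack so that exactly
  4 of 7 readings counts as meeting 4/7 under floating-point division.
- Duplicate (day, slot) readings keep the earliest; review windows are
  half-open `[start, start+7d)` aligned to enrollment.
- Zero-dose slots absorb mandated decrements as `capped` no-ops; empty
  slots are `insufficient`, never an error.
- Rejection sampling aborts with a clear error when the acceptance rate
  falls below 1% (infeasible moment configurations).
- Readings outside the study window are excluded from episode extraction
  with a warning, not silently dropped.

## Problem sizes used in validation

The test suite and drivers run the full study size (25 patients, 24 weeks,
~8,100 readings — fractions of a second per trial). Property suites use
derandomized generation: exhaustive rule-table equivalence over all
4-reading multisets from a 5-point glucose grid spanning every rule region
(×3 regimens), a 10⁴-window randomized safety-precedence search, 10⁴
Monte-Carlo replicates for the dose-response expectation, and a scalar
fixed-point iteration as the oracle for the noiseless closed loop.

## Known limitations

- The rule constants (consistency fraction, tier margin, urgent threshold,
  level-1 trigger count) approximate an unpublished proprietary algorithm;
  conclusions about *that* algorithm's exact behaviour cannot be drawn
  from this implementation.
- The linear patient model cannot exhibit overshoot-driven oscillation
  unless sensitivity, step size, or noise are pushed far beyond the
  defaults; stability results here do not transfer to strongly non-linear
  responders.
- Episode debouncing assumes one strip stream per participant; interleaved
  meters are merged by time only.
- BMI in the simulator follows a fixed small secular trend rather than an
  energy-balance model; it exists so summary tables have realistic shape.
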