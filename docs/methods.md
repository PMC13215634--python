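# Methods

`bracewear` measures orthosis adherence objectively from a temperature
sensor embedded in a knee brace, and quantifies how well day-level
self-report agrees with the sensor across aggregation levels. Because no
participant-level trial data are deposited, a synthetic-cohort generator
with full ground truth drives all validation; this note documents the
models, the defaults and why, and what the synthetic results do and do
not establish.

## 1. Synthetic cohort generator (`bracewear.simulate`)

### Wear schedules

Each participant wears the brace on a given day with probability
`p_wear_day` (default 0.7), at most one bout per wear day, with duration
drawn from a truncated normal (mean `bout_minutes_mean` = 70 min,
SD 30 min, floor = one sampling interval, whole minutes) — centred near
the advised "at least one hour per day". Bout starts are uniform over
07:00–21:00 and bouts are truncated at 23:59 by default
(`allow_midnight_spanning` exercises the midnight-split path). A sample
is "worn" iff its timestamp lies in the half-open interval [don, doff),
so transitions are never double-counted.

Participants are deliberately heterogeneous: per-participant wear
propensity (`p_wear_day_between_sd` = 0.15), typical bout length
(`bout_mean_between_sd` = 40 min) and multiplicative recall gain
(`report_gain_between_sd` = 0.25) vary across the cohort. The motivation
is internal consistency of the emulated study: a cohort in which
average-daily agreement across participants is far higher than daily
agreement (the study's headline pattern) is only possible when
between-participant differences in wear dwarf the reporting error, and a
cohort in which some participants under-report minutes while others
over-report requires participant-level recall gains on both sides of 1.
A homogeneous generator reproduces neither.

### Thermal model

The sensor temperature follows first-order Newtonian relaxation, stepped
per 10-minute sample:

    T_i = target_i + (T_{i-1} − target_i) · exp(−Δ/τ)

with target = skin temperature (32 °C) and τ_on = 15 min while worn, and
target = ambient with τ_off = 20 min while off. Ambient is a diurnal
sinusoid (mean 22 °C, amplitude 2 °C, peak 15:00), optionally perturbed
by transient +8 °C "hot car" steps (Poisson rate 0.1/day, 40 min,
restricted to non-wear periods by default so that false-positive
behaviour can be isolated). The wear state for the step ending at sample
*i* is the mask at the step's start, so a bout beginning exactly on a
sample shows its first rise one sample later — a sharp spike on donning,
a plateau near skin temperature, and a sharp fall on doffing. Gaussian
sensor noise (SD 0.2 °C) is added and values are quantized to 0.1 °C,
the sensor's stated precision. The noise-free trace matches the
closed-form per-segment solution to within half a quantization step.

### Self-report model

For a true wear day the log records
`round_rnd(max(0, gain_i · true + N(0, σ_recall)))` with σ_recall =
20 min and rounding to 15 min (round half away from zero — everyday
reporting behaviour, and deterministic). A true no-wear day is reported
as a phantom wear day with probability 0.15 (duration drawn from the
bout distribution), otherwise 0. Entries go missing with probability
`p_missing_log` (0.05); `trial_config()` instead concentrates
missingness in one participant (rate 0.31 vs 0.008 elsewhere, ≈13 of
~16 absent entries in one person) to emulate the observed pattern of
missing daily logs.

All draws come from named per-participant RNG substreams keyed off the
master seed, so resizing the cohort never changes earlier participants.

## 2. Wear detection (`bracewear.detect`)

Detection is gradient-based: donning and doffing are temperature spikes
and drops in the first-differenced trace, which makes the detector
invariant to ambient offsets and slow diurnal drift (a level-based
threshold is deliberately not offered). A DON fires at the first sample
of any run of at most `confirm_samples` (2) consecutive positive
differences whose sum reaches `theta_on` (1.5 °C); DOFF analogously with
`theta_off`. The noise-free donning step from ambient is
10 °C × (1 − e^(−10/15)) ≈ 4.9 °C — more than three times the
threshold — while quantized sensor noise (SD 0.2 °C, so difference SD
≈ 0.28 °C) crosses it only in a few-per-million windows. The reference
algorithm's exact spike/drop magnitudes are not published; these
defaults are this package's own calibration, all config-exposed.

Events are paired by a state machine (NOT-WORN → DON opens, next DOFF
closes; repeats ignored; a leading DOFF closes a bout open at the record
start; a bout open at the record end closes at the last sample). Bouts
shorter than `min_bout` (10 min) are dropped, then bouts separated by at
most `merge_gap` (10 min) merged. Series are split at any sampling gap
larger than twice the sampling interval and processed per segment, so
outages never produce spurious gradients. Event instants sit at the
first sample of the triggering run, giving a documented ±1-sample
uncertainty per transition (≤ 20 min/day error per bout at 10-minute
sampling).

**Plateau confirmation (on by default).** A rare noise-plus-drift
excursion (measured ≈2 per 100 simulated 42-day no-wear records) can
cross the trigger; because the closing rule would then run the bout to
the record end, a single such event would cost thousands of false
minutes. A DON is therefore cancelled unless, within the first hour
after donning, the trace sustains a rise of `plateau_rise` (3 °C) above
the pre-don level for `plateau_samples` (2) consecutive samples
(shortened for bouts briefer than that; skipped for bouts already open
at the record start, which have no rise to confirm). Noise cannot
sustain such a rise, so false-positive wear on never-worn noisy records
drops to ≈0 min/day. At the 3 °C default the check still accepts +8 °C
ambient steps; raising `plateau_rise` above the step amplitude (e.g.
7.5 °C) rejects hot-car transients as well — an ambient step can never
lift the trace by more than the step itself, while skin contact keeps
driving it ~10 °C above ambient — at the cost of slightly slower
confirmation of genuine bouts (see
`results/detection_validation.csv`).

## 3. Aggregation (`bracewear.aggregate`)

Interval minutes are attributed to calendar days by overlap with
[00:00, 24:00) local time, splitting midnight-spanning bouts exactly;
daily totals conserve interval durations to the minute. Sensor days with
no detected wear are observed zeros; self-report days are missing only
when no log entry exists. The outcome measures are: daily minutes; 3-
and 7-day trailing rolling averages (labelled by their last day, emitted
only where every window day is observed); cumulative minutes; average
daily minutes (total / observed days — each source over its own observed
days); and days worn (observed days with non-zero wear).

## 4. Agreement (`bracewear.agreement`)

At each level an aligned panel pairs sensor and self-report values
(per participant-day at repeated levels, one pair per participant at
aggregated levels; pairs with either side missing are dropped).
Differences are oriented self-report − sensor, so over-reporting is a
positive bias.

* **CCC** — Lin's moment estimator on the pooled pairs,
  `2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with divisor-n moments, banded
  <0.5 poor, 0.5–0.75 moderate, 0.75–0.9 strong, >0.9 excellent (both
  banding boundaries inclusive on the lower band). A
  variance-components alternative for repeated levels
  (`use_vc_ccc`) fits a subject random-intercept model with the method
  effect as a fixed shift and returns
  σ²_subj/(σ²_subj + σ²_resid + Δ²/2); the subject-by-method
  interaction is folded into the residual.
* **Limits of agreement** — mean difference ± 1.96 × sample SD. At
  repeated levels the default is the naive pooled SD of all daily
  differences (consistent with reporting very wide daily limits); the
  multiple-observations-per-individual correction
  (`rm_loa_correction`) recovers the between-subject variance component
  from a one-way ANOVA of the differences and adds it to the
  within-subject component.
* **Confidence intervals** — repeated levels use a participant-level
  cluster bootstrap (resample participants with replacement keeping all
  their days, percentile 2.5/97.5, default B = 2000, seeded);
  aggregated levels use the Fisher z-transform with n = participants.

Known limitation: with only ~10 clusters the percentile cluster
bootstrap undercovers — in this package's own calibration study
(subject random intercepts sized to the emulated cohort, true CCC
0.714, 10×42 panels) the nominal 95% interval covers ≈0.87–0.88. This
is the well-known few-cluster behaviour of the percentile method;
interpret the repeated-level CIs as approximate with small cohorts.

## 5. Sensitivity analyses (`bracewear.sensitivity`)

Two scenarios recompute every estimate from scratch (no caching):
missing self-report days imputed as observed zeros (self-report only —
sensor zeros are measurements), and exclusion of the participant with
the most missing log days (argmax, ties broken by id). Imputation never
removes pairs; exclusion never adds them; with no missing data all
scenarios coincide exactly.

## 6. Problem sizes and numerical choices

Validation studies use: 50 participants × 42 days for noise-free
detection recovery; 100 single-participant 42-day records for noisy
recovery and false positives; 200 replicates of a 10 × 42 grid for the
rolling-average variance law; 50 trial-scale cohorts for the
directional checks; and 300 cohorts × 500 resamples for bootstrap
coverage — sizes chosen so the full validation suite runs in a few
minutes on one CPU while keeping Monte-Carlo error well below the
margins being tested. Degenerate inputs are handled explicitly: CCC is
undefined (an error) when both vectors are constant; a CCC of ±1 yields
a point interval with a warning; zero-spread differences give
zero-width limits; all-missing series are rejected.

## 7. What the generator does not emulate

First-order relaxation with a single skin temperature ignores local
sweating, brace repositioning, partial skin contact and battery
effects; confounders are square ambient steps; self-report errors are
conditionally independent across days (no weekly recall batching, no
end-of-study fatigue); and wear is at most one bout per day by default.
Passing validation therefore shows the pipeline recovers truth under
the stated physics and bias models — not that the specific detector
thresholds are optimal for any particular physical sensor, which would
require bench validation against observed donning events.
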