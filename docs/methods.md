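# Methods

This note documents the models, the numerical choices and the limitations
of `habitcoach`: what each stage assumes, which parameters matter, what the
synthetic data does and does not emulate.

## Growth classification

BMI (kg/m²) is converted to an age- and sex-specific z-score with the LMS
method: `z = ((x/M)^L − 1)/(L·S)` where `L` is the Box–Cox skewness power,
`M` the reference median and `S` the coefficient of variation. For
`|L| < 1e-5` the implementation switches to the exact `L → 0` limit
`z = ln(x/M)/S`; the raw closed form loses about `|L|·ln²(x/M)` of accuracy
near zero, so the explicit switch keeps the transform continuous to below
1e-9 across the whole `L` range. Ages between tabulated months are linearly
interpolated on `(L, M, S)`, the standard practice for monthly growth
tables. Measurements with `|z| > 5` are logged as suspect (device or entry
error) but not dropped.

Nutritional status uses the school-age convention of five bands with
boundaries at z = −3, −2, +1, +2; every boundary belongs to the less severe
band (so z = −2 is *normal*, z = +2 is *overweight*). Fat-mass % and
waist-based (abdominal obesity) categories use the generic ordinal
classifier `categorize_by_cutoffs` with user-supplied reference cut-offs —
computing those reference cut-offs from population data is out of scope.

**The bundled reference table is synthetic.** `data_files/lms_bmi_synthetic.csv`
contains smooth, monotone, order-of-magnitude realistic L/M/S values for
108–155 months, both sexes. It makes the package self-contained and the
simulator's ground truth exact (children are generated in z-space and
converted through this same table), but its z-scores are *not* comparable
with any published growth standard. Real analyses must supply a real
reference CSV (`sex,age_months,L,M,S`) via `lms_table` in the config.

## Behaviour stratification

Each variable's rule has a direction (`higher_is_worse` for e.g. sweets
frequency, `lower_is_worse` for steps, sleep, fruit) and two cut-offs;
boundary values join the less severe band. The shipped cut-offs are
programme-editable placeholders informed by common school-age guidance
(60 min/day of activity, ≈9 h sleep, daily fruit/vegetables, limited
sweets); a real deployment calibrates them against its own baseline survey,
which is where such thresholds normatively come from. The food-frequency
mapping turns category strings into weekly frequencies with the midpoint
convention for ranges ("2-3/week" → 2.5). The PAQ-C composite is the
unweighted mean of its (default 9) 1–5 items. Physical-activity goals grow
from the individual baseline by a weekly percentage increase, capped at the
target level: `min(baseline·(1+δ)^week, target)`.

## Trend risk detection

The detector runs per child × variable on daily data and assumes: daily
cadence with explicit missing markers, weekly (period-7) seasonality,
additive noise, and a piecewise-linear underlying trend.

1. **Artifact screen.** A day whose raw day-to-day slopes in and out both
   exceed `max_slope` with opposite signs is a single-day excursion — the
   signature of a device dropout or double-sync — and is reported as an
   `ignored_too_steep` artifact and masked. This implements the rule that
   implausibly steep slopes are ignored rather than treated as behaviour.
2. **Gaps.** Missing runs of ≤ 2 days (configurable) are linearly
   interpolated; longer gaps split the series and only the most recent run
   of at least `2·period` days is analysed.
3. **Decomposition.** Classical additive decomposition (statsmodels
   `seasonal_decompose`, period 7, trend edges extrapolated) so the trend
   covers every day.
4. **Segmentation.** Exact piecewise-linear regression of the trend:
   dynamic programming over all breakpoint placements minimises the total
   per-segment OLS error; for each candidate segment count the optimum is
   exact (verified against exhaustive search). The segment count k ≤
   `max_segments` (default 3) is chosen by minimising
   `SSE_k + penalty·(k−1)` with default penalty
   `2·period·Var(residual)`: the moving-average trend carries day-level
   noise averaged over `period` days with matching autocorrelation, so the
   white-noise parsimony penalty must be inflated by the filter length —
   without the inflation, flat noisy series get split and produce spurious
   risk detections.
5. **Classification.** |slope| < `min_slope` → harmless; |slope| >
   `max_slope` → artifact-steep (ignored); otherwise unhealthy if the sign
   matches the variable's harmful direction (descending for steps/active
   minutes/sleep). Defaults for steps: 100 and 2000 steps/day per day —
   order-of-magnitude plausible and fully configurable.
6. **Reference point.** Coarsely, the start of the latest unhealthy
   episode (consecutive unhealthy segments). Because a discontinuous
   per-segment fit on a smoothed trend localises a slope break only to
   within ~±5 days, a precision stage then re-estimates the break day on
   the raw (gap-filled) values inside the episode window: a broken-line
   model `level (+ day-of-week effects) + slope·max(t−c, 0)` is profiled
   over integer candidate days c and the maximum-likelihood c wins. Two
   refinements matter. Hard zeros are treated as *left-censored* (a step
   count cannot go below zero), handled by EM imputation under a Gaussian
   noise model, and a trailing segment pinned at zero is kept inside the
   window as censored evidence of the continuing decline. And when the
   preceding segment is classified stable (that is what no-risk means),
   the pre-break slope is fixed at zero, which sharpens the estimate; when
   it is not, the pre-break slope stays free. Known limitation: a
   pre-break drift that is non-zero yet below `min_slope` biases the
   refined break day by a few days.
7. **Forecast and verdict.** The forecast is the OLS line of the trend
   from the reference point to the series end, continued `horizon` (default
   7) days. The unhealthy behaviour "continues in the predicted values"
   exactly when the final fitted segment is itself unhealthy — then the
   verdict is `unhealthy_trend_confirmed_by_forecast`, otherwise
   `unhealthy_trend_not_confirmed`. Both unhealthy verdicts are exported
   to the coaching engine (as motivation triggers and plan rationale); they
   do not override the flag scheme.

Detection tests use 84-day (12 school-week) series, the package's default
monitoring window.

## Weekly coaching

Flags come from stratifying each behaviour's source variables (a
multi-variable behaviour takes its most severe flag); behaviours with no
resolvable data are flagged yellow and logged (or rejected under the strict
policy). Mission selection per dimension orders behaviours by
(current flag severity, length of the consecutive red run ending at the
current week, configured order) and returns the lowest-numbered catalogue
mission targeting the winner; an all-green dimension still receives the
first behaviour's mission as maintenance. The plan assessed from week T
applies to week T+1 (ISO weeks). Carer feedback validates outcomes;
conflicting reports resolve educator-over-family (logged); missions without
feedback stay pending until the end of the following week, then count as
not completed. Points of completed missions accumulate per ability
(defaults: physical activity → dexterity, diet → discipline, education →
intelligence — the mapping is configuration, as the authoritative
mission-to-ability table is programme content). Ability percentages sum to
100 whenever the total is positive.

## Synthetic cohort simulator

The generator exists to make every engine stage testable with known ground
truth. Per child: daily series = baseline (child-level Gaussian) + zero-mean
day-of-week pattern + piecewise-linear trend from the changepoint spec +
Gaussian daily noise, clipped at zero, with single-day dropout artifacts at
a configured daily rate. Questionnaire answers invert the stratification
rules — sample a risk band, then a value (or frequency category) inside
it — so flag ground truth is exact by construction. Anthropometry samples a
nutritional status from configured prevalences, draws z inside that
status's band (|z| capped at 3.5 to stay in the LMS-invertible range), and
converts through the bundled table, so status ground truth is exact.

Defaults mirror a baseline school survey of the target age group: 11.7%
obesity and 17.1% overweight prevalence, 58.7% girls, ages uniform on
108–155 months, mean baseline 5,170 steps/day, and a 74% mission-adherence
probability. The intervention model is deliberately minimal: each assigned
mission is adhered to with a fixed probability, and an adhered mission
moves its target variable toward an interior point of the green band by a
configurable fraction of the gap (default 1.0, i.e. into the band), with
small week-to-week drift on all variables.

What the simulator does **not** emulate: intraday accelerometry, seasonal
(school-holiday) structure beyond the weekly cycle, reporting biases in
questionnaires, correlated behaviours within a child, or behaviour-change
psychology beyond the Bernoulli adherence model. Passing tests therefore
demonstrate the engine's logic and statistical behaviour under its stated
assumptions, not effectiveness on real cohorts.

## Numerical choices and degenerate inputs

- All randomness flows from integer seeds through `numpy.random.default_rng`;
  nothing reads the clock, so equal seed ⇒ identical output.
- Segment OLS uses prefix-sum normal equations (O(n²) for all spans); SSE
  values are clipped at zero against roundoff; segments need ≥ 2 points.
- Dates are calendar days without time zones; weeks are ISO-8601
  (`YYYY-Www`), with 53-week years handled.
- File writes are atomic (temp file + rename): a validation failure never
  leaves a partial output.
- Degenerate inputs raise typed errors: non-positive weight/height/measure,
  series shorter than two periods, unordered cut-offs, unknown food
  categories, feedback for unassigned missions, empty cohorts.
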