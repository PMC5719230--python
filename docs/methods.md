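# Methods

## The task and its mechanics

The Stop Signal Task presents two-choice go trials; on 25% of trials a
visual stop signal follows the go stimulus after a stop-signal delay (SSD)
and the participant must withhold the response. A session is five blocks of
48 trials (240 trials, exactly 12 stop trials per block — the stop count is
deterministic per block, not a Bernoulli draw, and stop positions are
shuffled uniformly within each block). Stimuli are displayed for 900 ms;
fixation (500 ms) and intertrial intervals (500–1000 ms) are carried as
metadata only — no real-time behavior is simulated.

**Staircases.** SSDs are adapted by four independent 1-up/1-down staircases
assigned to stop trials round-robin, with initial SSDs {50, 150, 250, 350}
ms, step 50 ms, and bounds [0, 800] ms. A successful inhibition raises that
staircase's SSD by one step; a failed stop lowers it. This is the simplest
scheme that samples across the inhibition-probability-by-SSD space while
concentrating trials near each staircase's 50% point; the exact scheme used
in deployed task software varies, so step size, initials and bounds are all
configurable. Staircase state persists across a participant's sessions by
default (a longitudinal adaptive task carries its calibration forward);
`reset_staircases_per_session` restores independence.

**Scoring (points variant).** A correct go response earns
`0.2 × bonus × (800 − RT)` points, floored at zero for responses slower
than 800 ms. The bonus multiplier starts at 1, rises by 1 after every 3
go-type responses, and drops by 3 (floored at 1) when a stop trial is
failed after the signal appeared. A successful inhibition earns no points
but keeps the bonus. A response emitted *before* the signal would have
appeared is scored exactly like a go response — the participant saw, to all
appearances, an ordinary go trial — while the log still marks the trial
`stop_presignal` so analysis can treat it as a stop-trial failure. Points
are real-valued internally; `display_points` rounds half-up for display.
Scores reset per session; the high score persists.

## The race model and the simulator

The independent horse-race model treats the go and stop processes as
independent racers: a response escapes inhibition iff the go finishing time
is less than SSD + stop latency. The simulator draws go finishing times
from an ex-Gaussian (the standard positively skewed RT family), stop
latencies from a normal truncated at zero, and emits a response iff the go
time beats the stop finish and lands in the 900 ms display window.
Responses faster than the SSD are `stop_presignal`. Go trials lapse into
omissions with a small probability, and a small choice-error rate produces
`go_error` responses.

Defaults (per participant; chosen once as field-plausible values):

| parameter | default | why |
| --- | --- | --- |
| go ex-Gaussian μ, σ, τ | 380, 50, 120 ms | mean ≈ 500 ms, median ≈ 470 ms — typical choice-RT range for web samples |
| stop latency mean, SD | 270, 20 ms | true SSRT generator; between-participant spread N(270, 25) |
| lapse / choice-error prob. | 0.02 / 0.02 | rare omissions and miscategorizations |
| optional-phase daily hazard | 0.160 / 0.155 / 0.115 (nongame / points / theme) | constant per-day dropout giving expected session counts near 7.4 / 7.5 / 8.0 for conforming participants — realistic variant-level spread, configurable per day |
| questionnaire VAS mean at s1, drift | 56 / 59 / 53; −2, −2, −0.67 per session | emulates ratings in the mid-50s declining a few points by session 4, with the themed variant flattest |
| loss-of-focus rate | Poisson, ≈0.95/session | rare tab-switch events |

Every latent quantity later estimated (true SSRT, hazard, questionnaire
mean, focus rate) is written to a truth table, so recovery is testable. The
study design is 4 compulsory daily sessions plus up to 6 optional days with
a geometric (memoryless) dropout decision each optional day; the full
10-item questionnaire is delivered on sessions 1, 4, 7 and 10, the 5-item
short form otherwise. Optional non-conformance injection slips one
compulsory-phase day by 1 day (producing loosely conforming participants)
or 2 days (non-conforming).

What the simulator does **not** emulate: practice and fatigue effects
within or across sessions, SSRT drift, time-of-day effects, reminder or
payment effects on dropout, day-varying hazards shaped like real attrition
curves (a constant hazard is the default; a per-day vector is accepted),
and any dependence of questionnaire answers on actual task performance.
Passing recovery tests therefore shows the estimators are consistent with
the race model and the design — not that real cohorts satisfy either.

## SSRT estimation

Per session, in order:

1. **Filter**: response trials with RT < 150 ms are removed (anticipatory);
   non-response trials are kept.
2. **Race-model screen** (first failure is the recorded reason):
   `race_rt_order` — the median failed-stop RT must be *faster* than the
   median go RT. Study protocols sometimes word this rule backwards
   relative to the race-model prediction; the default implements the
   standard direction, and `verbatim_rt_rule=True` implements the inverted
   wording literally. The two are not silently reconciled.
   `ssd_rt_corr` — Spearman ρ of SSD against per-SSD median failed-stop RT
   must be strictly positive. `ssd_acc_corr` — Spearman ρ of SSD against
   per-SSD inhibition proportion must be strictly negative. Sessions with
   fewer than 8 stop-trial responses or fewer than 3 distinct SSDs are
   `insufficient_data`. Failed-stop medians are taken overall (not per
   SSD) for the RT-order check.
3. **Inhibition function**: logistic P(respond | SSD) fitted by maximum
   likelihood with the slope constrained ≥ 0 (monotone by construction);
   SSD50 is where the fitted probability crosses 0.5. Complete separation
   (all response SSDs above all inhibition SSDs) is flagged non-converged
   and SSD50 falls back to the midpoint between the highest all-inhibit and
   lowest all-respond SSD. `stop_presignal` trials count as responses by
   default (the go process won the race); a switch drops them.
4. **Subtraction**: SSRT = median go-response RT − SSD50. The subtraction
   convention is the standard median-based reading of the 50%-inhibition
   method.

Participant-level SSRT is the mean over valid sessions among the first
four; a participant with no valid compulsory session is excluded from SSRT
comparisons only. The coefficient of variation is 100 × SD(go RTs, n−1
denominator) / mean(go RTs). Participants whose mean go RT or go accuracy
lies more than 4 interquartile ranges from the group median are excluded
from analysis entirely; a degenerate zero IQR keeps only exact-median
values and warns.

**Estimator bias.** Under the simulator's defaults the estimand of the
pipeline (conditional-median go RT minus the SSD50 of the compound race
psychometric, distorted slightly by lapses and the logistic approximation)
sits a few ms below the true mean stop latency, and the staircase-sampled
logistic fit adds a further small negative bias: recovery runs show a mean
error near −15 ms with a recovery slope ≈ 0.95. This is inherent to the
SSD50 method with skewed go distributions, well inside the ±20 ms band the
recovery tests enforce, and is left undisguised rather than corrected.

## Engagement and attrition

Questionnaire items are 0–100 visual-analog scores (a 500-pixel line at
ingest, `normalize_vas`); items 2, 3, 6 and 8 are negatively keyed and
reverse-scored (x → 100 − x) before averaging over the delivered form's
items. The short form is items {1, 2, 5, 8, 9} — the complement of the
long-only items. The combined score is the mean of the session-1 and
session-4 scores (both long-form); a participant missing either is dropped
from combined analyses.

Conformance: `conforming` = first four completed sessions on days 1–4;
`loose` = four sessions within the first five days (starting day 1);
everything else `non`. The classes are mutually exclusive and exhaustive.
Attrition is summarized as mean sessions completed per variant (t-based 95%
CIs; the CI method is a package choice) and the percentage completing at
least k sessions, k = 1..10. Sessions started but not finished are excluded
before any of this via the `completed` flag.

## Inference

- **Survival**: Kaplan–Meier over sessions completed (lifelines);
  participants reaching the 10-session cap are right-censored there by
  default, with an event-mode switch. When the censoring time coincides
  with the latest exit time the log-rank statistic is identical under both
  modes (the final-time contribution has observed = expected and zero
  hypergeometric variance), so the choice matters for descriptives, not
  the test.
- **ANOVAs**: one-way F from the sums-of-squares decomposition with partial
  η² = SS_between / (SS_between + SS_within); the session × variant design
  uses pingouin's mixed ANOVA (two within-levels, so sphericity holds
  trivially).
- **Post hoc t**: Student's pooled-variance t by default (df = n₁ + n₂ − 2,
  the convention matching reported degrees of freedom), Cohen's d from the
  pooled SD, 95% CI on the mean difference; a Welch switch is provided. No
  multiple-testing correction anywhere, mirroring single-test reporting.
- **JZS Bayes factor**: H0: δ = 0 versus H1: δ ~ Cauchy(0, r), r = 0.707
  (a medium-large prior that penalizes small effects). BF10 =
  ∫ f_nct(t; ν, δ√N) dCauchy(δ) / f_t(t; ν) with N = n₁n₂/(n₁+n₂),
  integrated adaptively at tolerance 1e−8, split at zero; the noncentral-t
  density is evaluated on the log scale and non-finite underflow treated as
  zero density. Evidence labels: BF ∈ [1/3, 3] no support either way;
  [0.1, 1/3] positive (for equality); [0.01, 0.1] strong; < 0.01 decisive —
  and symmetrically above 1 for a difference. Tests verify ≤1% agreement
  with an independent fine-grid quadrature in the Zellner–Siow *g*
  parameterization and with pingouin's implementation.
- **Next-day return**: logistic regression (statsmodels MLE) of "returned
  the following calendar day" on that day's questionnaire score over the
  optional-phase decision days (sessions 4–9); Wald χ² = (β/SE)², OR =
  exp(β). Complete separation is detected by a threshold check on the
  predictor and reported, not hidden.
- **Power**: smallest integer n with noncentral-χ²(df, λ = nφ²) power ≥
  target at the central-χ² critical value, found by bisection (exactness
  verified at n and n−1); `multiple_of` rounds up for equal group sizes.

## Numerical and scale choices

Problem sizes in the test suite are chosen to keep the full run in tens of
seconds while leaving Monte-Carlo margins wide: recovery uses 50
participants × 4 sessions × 240 trials; type-I calibration uses 1,000 null
cohorts of 97 × 3 participants (attrition counts only — the trial level is
irrelevant to those tests and is not simulated there); the staircase
equilibrium check uses 4,000 trials after a 500-trial burn-in. All
randomness flows from a root seed through named `SeedSequence` substreams
(one per participant), so cohorts are reproducible byte-for-byte and
participants independently so. JSON reports round floats to 6 digits for
byte-stable output.

## Known limitations

- The inhibition-function method is one of several SSRT estimators;
  integration (mean-SSD) and hierarchical Bayesian estimators are out of
  scope.
- The race-model screen's correlation checks are sign tests on Spearman ρ
  without a significance threshold; on well-specified data they still
  exclude a small fraction of sessions (noise in 8–16 per-SSD bins), which
  the tests monitor but deliberately do not force to zero.
- Constant per-day hazards make dropout memoryless; real attrition curves
  typically fall steeply after the compulsory phase and flatten later.
- The simulator's questionnaire model is a clipped normal around a linear
  trend; it reproduces means and declines, not item covariance structure.
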