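# Methods

This note documents the models, rules and numerical choices behind each stage
of the pipeline, the assumptions of the synthetic-data generator, and the
limitations a user should keep in mind when extrapolating from passing tests
to real CGM/EMA data.

## Study design model

The design is a two-phase crossover. Group A runs the low-frequency schedule
(3 EMAs/day for 10 days) then the high-frequency schedule (6 EMAs/day for 5
days); group B the reverse. Notification windows are fixed daily clock-time
blocks between 09:00 and 21:00: three 4-hour blocks for 3/day
(09:00–12:59, 13:00–16:59, 17:00–21:00) and six 2-hour blocks for 6/day.
One notification is drawn per window per day, uniform at 1-minute resolution
with **both window bounds inclusive** (a 12:59 end admits a 12:59 draw and not
13:00) — the literal reading of printed window bounds. Participants have 30
minutes to start; a started session runs about 5 minutes.

Timestamps are naive local clock times. Daylight-saving transitions are out
of scope: synthetic days are uniform 1440-minute days.

Counterbalancing: the battery has 3 cognitive domains × 2 tests. Within each
phase, each domain contributes a balanced sequence (each test exactly half
the phase's occasions — 15 of 30) shuffled by a seeded RNG. No published
algorithm exists for this step; exact balance plus seed reproducibility is
the contract, and any balanced shuffle satisfies it. Over the full crossover
each test is administered 30 times, giving at most 60 split-half
measurements per test per participant. An onboarding session on the day
before the first analysis day is represented only as a plan attribute; it is
never an analysis occasion.

## Hypoglycemia detection

Working on the sample grid (nominal 5-minute cadence, larger gaps permitted):

- **Onset**: a run of consecutive samples below threshold (default 70 mg/dL)
  containing at least two samples ≥15 minutes apart with no intervening
  sample at/above threshold. "≥15 consecutive minutes" is evaluated as the
  span between the first and last qualifying samples.
- **Persistence**: once begun, an event survives excursions at/above
  threshold shorter than 15 minutes.
- **End**: the event terminates at the first recovery run (≥2 samples
  at/above threshold, ≥15 minutes apart, no intervening low sample); the
  event's end timestamp is the **last sub-threshold sample before that run**,
  so duration measures time spent low. Capture windows reference this end.
- A value exactly at threshold counts as recovery. The printed rules use
  strict "<70" for hypoglycemia and ">70" for recovery, leaving 70 itself
  undefined; treating it as recovery makes the two conditions exhaustive.
- An event still below threshold when the trace ends is emitted with end =
  last low sample; requiring a confirmed recovery at end-of-wear would
  silently drop real (and injected) episodes.

The detector is a pure function of the trace and is property-tested for exact
agreement against a brute-force reference that enumerates candidate
onset/recovery index pairs directly from the rule statements.

**Exclusions** (sensor-error screen): within an event's [start, end], an
adjacent-sample jump >40 mg/dL flags `jump_artifact`; an inter-sample gap
>20 minutes flags `missing_data`. The consensus criterion behind this screen
names no numbers; 40 mg/dL per 5-minute step is far outside physiological
rates of change, and 20 minutes means three consecutive missed samples. Both
are configuration-exposed. Flagged events are retained in outputs but never
counted downstream.

**Daytime restriction**: the capture analysis considers events overlapping
08:00–22:00 (one hour of padding around EMA delivery hours) on any calendar
day. Overlap, not containment, is the default: the padding expresses
proximity to EMA hours, and an episode straddling 08:00 is exactly as
capturable by a 09:05 EMA as one starting at 08:00. Containment is available
as an option. **Eligibility**: cadence-weighted coverage of ≥72 h (exactly
72 h is eligible — the exclusion rule is written as "<3 days").

## Capture classification

A completed session captures an episode when (1) the episode's interval
intersects [start − 60 min, start], (2) the episode begins in [start, end],
or (3) it begins in (end, end + 15 min]. All stated bounds are closed
("within 60 minutes" includes a tie at exactly 60). Criterion 1 deliberately
admits episodes still ongoing at session start. Per schedule phase, captured
counts are unique-episode counts (an episode seen by two EMAs counts once);
events are attributed to a phase by the calendar date of their start, phases
being contiguous date blocks. The analysis-set filter retains participants
with overall completion ≥50% — computed over all 60 scheduled occasions of
both phases — and CGM coverage ≥72 h.

## Cognitive scoring

- `medianRTc`: median reaction time over correct trials only (the trailing
  "c"), omissions excluded; even-count medians use the midpoint.
- `accuracy`: 100 × correct/total; omissions count as incorrect.
- `d_prime`: Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate) with the log-linear
  correction (add 0.5 to hit/FA counts, 1 to denominators) applied to **every**
  administration, not only extreme ones — always-on correction keeps the score
  finite at perfect rates without introducing a discontinuity between corrected
  and uncorrected administrations. Omitted responses on target trials are
  misses.
- Split halves partition trials by 1-based presentation-index parity ("odd"
  contains trial 1). For the CPT, halves split over all trials, with d′
  computed per half.

## Reliability model

Half-scores follow an intercept-only two-level nested decomposition: sessions
within participants, halves as within-session replicates. Reported components
are `var_bp` (participant level) and `var_wp` (session + residual, pooled —
the formula below needs only their sum). Between-person reliability for n
averaged measurements:

    reliability = var_bp / (var_bp + var_wp / n)

with n = the average number of half-score measurements per participant over
the analyzed subset (fractional n is kept; no rounding), maximum 60.

**Estimator.** The default is a method-of-moments nested ANOVA using Searle's
expected-mean-squares coefficients, valid for unbalanced data, with negative
solutions truncated at zero. REML (statsmodels `MixedLM`) is exposed as
`method="reml"` as a cross-check; on balanced data with interior solutions
the two coincide (tested to 1% relative tolerance). MoM is the default
because the estimator inside the participant-level bootstrap must be cheap:
it reduces to per-participant sufficient statistics, which makes 10,000
resamples (and the coverage Monte-Carlo around them) a vectorized summation
rather than 10,000 iterative model fits.

**Single-session data** (one session per participant, both halves present)
cannot separate session from residual variance, and is the regime where the
reliability formula must reduce to Spearman-Brown. Here the components come
from the split-half moment estimator: var_bp = the sample covariance of even
and odd half-scores, total variance = the geometric mean of the two half
variances. With n = 2 this makes the formula *algebraically identical* to
2r/(1+r) with r the Pearson correlation of the halves — the classical
equivalence, which the test suite pins at 1e-8. Truncation at zero applies
when r < 0 (reliability is then reported as 0).

**Bootstrap.** Percentile intervals (2.5/97.5) from resampling participants
with replacement; each resample re-estimates components and its own n_eff.
Duplicated participants are treated as distinct clusters, the standard
cluster-bootstrap convention. Resamples with no score variance (undefined
reliability) are redrawn and the redraw count recorded. The percentile
method was chosen for transparency; for reliabilities near 1 it is mildly
conservative-to-anticonservative depending on skew, and the coverage
Monte-Carlo in the acceptance suite measures it directly (typically 92–95%
at 100 participants for a true reliability of 0.9).

Missing halves are dropped row-wise; the estimators tolerate the resulting
imbalance. Per-schedule reliabilities use only that schedule's halves
(n_eff from the subset), alongside a pooled estimate.

## Schedule comparison

Participant-level means are computed first (mean over a participant's
completed administrations within a schedule); the table reports the mean and
SD of those participant-level means, making the table invariant to permuting
sessions within a participant. Each metric gets a paired two-tailed t test:
t = mean(d)/(sd(d)/√n) with the (n−1)-denominator SD, p from the t
distribution with n−1 df, and Cohen's dz = mean(d)/sd(d) = t/√n (an
algebraic identity asserted per emitted row). Differences are oriented
3/day − 6/day. Participants missing a metric under either schedule are
dropped pairwise for that metric. No multiple-testing correction is applied.
Display rounding: 0 dp for milliseconds, 1 dp for percentages, 2 dp for d′,
dz and reliability.

## Synthetic-data generator

The generator's purpose is a **truth registry**, not physiological fidelity:
every quantity the pipeline estimates exists in the generator as a known
parameter or a registered event.

- **Glucose background**: discretized mean-reverting AR(1),
  x_{k+1} = (1−θ)x_k + ε, θ = 0.05 per 5-minute step (≈70-minute
  reversion half-life), stationary mean 150 mg/dL and SD 25 mg/dL. The SD is
  deliberately moderate — real T1D traces are more variable — so that
  spontaneous sub-70 excursions are negligible and essentially every detected
  event is an injected, registered one.
- **Injected events**: Poisson with 0.51 events/day (the rate reported for
  daytime hypoglycemia in the pilot cohort), starts uniform within
  08:00–22:00 (a flag enables nighttime injection for testing the daytime
  restriction), duration normal around 40 minutes (floor 20), nadir uniform
  in 54–66 mg/dL, ≥30-minute separation enforced by redraw. Each event
  overrides the background with a V-shaped dip from 68 mg/dL at the edges to
  the nadir, so all in-event samples are below threshold by construction;
  grid-aligned start/end go into the truth registry.
- **Artifacts and dropouts**: single-sample jumps of ±45–90 mg/dL with
  probability 0.002 per sample; samples dropped with probability 0.01; values
  clamped to the 40–400 mg/dL reporting range.
- **Sessions**: independent Bernoulli completion per occasion, probability
  0.857 (3/day) and 0.817 (6/day) — the pilot's completion rates; start
  uniform in (notification, notification + 30 min], duration uniform 4–6
  minutes.
- **Cognitive scores**: per test, half-score = grand mean + person effect +
  session effect + residual, with defaults on the pilot's score scales
  (e.g. Choice RT 731 ± 114 ms between persons). Reaction-time trials are
  realized as the latent half-score plus a symmetric jitter pattern whose
  median is exactly zero, so the realized decomposition equals the generative
  one — this is what makes 15%-relative-error parameter recovery a fair test.
  Accuracy trials are Bernoulli and CPT trials binomial signal-detection
  draws (hit rate Φ(d′/2), false-alarm rate Φ(−d′/2), ~80% targets), which
  add trial-sampling variance on top of the nominal residual and, for the
  CPT at 10-trial halves, bias corrected d′ downward relative to the latent
  value. Parameter-recovery claims therefore use the RT pathway or the
  direct half-score generator (`simulate_half_scores`).
- **Reproducibility**: one cohort seed expands to per-participant,
  per-stream substreams by an integer hash of (seed, participant index,
  stream); identical parameters and seed reproduce the cohort bit-for-bit,
  and any single participant can be regenerated alone.

What the generator does **not** emulate: meal/insulin dynamics, realistic
sensor error (MARD), compression lows, circadian glucose structure,
practice/fatigue effects on cognition, time-of-day effects, or any coupling
between glycemia and cognitive scores. Passing tests therefore demonstrate
correctness of the *rules and estimators*, not robustness to the messiness
of real participant data.

## Problem sizes in routine runs

The test and acceptance suites use cohort sizes chosen to make Monte-Carlo
checks statistically meaningful at desk scale: 1000 random traces for
detector–oracle equivalence, ±3 h at 1-minute resolution for the capture
truth table, 10 cohorts of 200 participants × 30 sessions for variance
recovery, 200 replications × 1000 bootstrap resamples for CI coverage, 200
participants for the event-rate calibration, and 500 participants for the
null-effect check on the schedule comparison. Production analyses of a
20-participant pilot are far below these sizes; the default pipeline
bootstrap uses 1,000 resamples with 10,000 available via configuration.

## Known limitations

- The nested ANOVA truncates negative components at zero, which biases
  variance estimates upward near the boundary (visible only when true
  between-person variance is ~0).
- Percentile bootstrap CIs at small participant counts (n ≈ 18) are wide and
  can fail to bracket the point estimate in pathological resamples; the
  estimate records redraw counts rather than hiding them.
- The detector's end-of-trace convention (no confirmed recovery required)
  slightly inflates event counts at sensor removal relative to a strict
  reading of the end rule.
- Events are attributed to schedule phases by start date; an episode
  beginning in the last minutes of one phase and captured by the next
  phase's first EMA is credited to the earlier phase.
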