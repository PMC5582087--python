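# Methods

`damsleep` analyzes *Drosophila* Activity Monitor (DAM) recordings from a
rotating-tube ("swing boat") exercise protocol. A DAM counts infrared-beam
crossings per recording interval for each of 32 flies; the pipeline turns
those counts into sleep, fragmentation, exercise-response and survival
statistics, and ships a simulator that generates the same kind of data
with known ground truth.

## Sleep scoring

Sleep follows the standard fly convention: any run of ≥ 5 consecutive
minutes with zero beam crossings is sleep. Maximal zero-count runs are
*sleep bouts*; a bout of ≤ 60 min is short-term ("fragmented") sleep, a
bout > 1 h is long-term sleep (the 60-min bout is short, by the "maximum
60 min" reading of the boundary). Canonical scoring runs on 1-min bins.
On 5-min bins (the display resolution of actograms) a zero bin
contributes 5 sleep minutes and a single zero bin already satisfies the
5-min rule; this mode is an approximation of 1-min scoring and results
carry the resolution they were computed at. Masked bins (non-status-1
monitor readings) are treated as missing and terminate runs; a fly-day
with more than 5% masked minutes is excluded from summaries.

Bout boundaries use half-open minute intervals: start = first zero
minute, end = one past the last zero minute. The detector is exactly
equivalent to a brute-force maximal-zero-run scan, and this equivalence
is asserted in the tests over 1,000 random series.

## Episodes and daily summaries

Each day is partitioned into four clock-time windows: night 22:00–04:00,
morning 04:00–12:00, siesta 12:00–16:00, evening 16:00–22:00 (ZT14–20,
ZT20–4, ZT4–8, ZT8–14 for lights-on at 08:00). Days run from lights-on
(ZT0). Because the morning window spans ZT0, its pre-ZT0 portion
(ZT20–24) is attached to the *following* day so each day's morning is one
contiguous block; a bout spanning a window edge is split pro-rata by
overlap, so per-episode sleep tiles the daily total exactly. Day
completeness is judged on the calendar ZT day: a recording that starts at
ZT0 therefore has a complete day 1 whose morning episode lacks only the
pre-ZT0 portion that was never recorded. Daily group values average over
all animals alive (and not excluded) on that day, so per-day n shrinks as
flies die.

## Death calling and survival

A fly is dead when its terminal immobility strictly exceeds 24 h; the
death time is the end of the last bin with a nonzero count (lifespan from
last observed movement), at the resolution of the recording bin.
Mid-recording immobility followed by resumed activity is never a death. A
fly with no counts at all is called dead at the recording start and
flagged `never_active` for manual review. Flies still active at the end
of the recording are censored there.

Kaplan–Meier estimation and the two-group Mantel–Cox log-rank test (with
the hypergeometric variance for ties) are implemented directly and
cross-checked in the tests against `lifelines` to 1e-9 on 200
mixed-censoring records; the log-rank null rejection rate is verified to
sit near its nominal 5% over 1,000 simulations. The KM median is the
smallest event time t with S(t) ≤ 0.5 and is reported as not-reached
(NaN) when the curve never drops that far. Median prolongation is
(treated − control, 100 × difference / control). The time origin is the
start of recording; if lifespans should instead count from eclosion, a
constant offset must be added by the caller.

## Exercise metrics

The stimulation protocol defaults to the swing-boat schedule: rocking
starts at ZT7 and lasts 30 min at 3 turns/min (30° displacement at 30°/s,
~17 s pause), 90 stimuli/day, exercise days 1–12. Exercise success for a
fly-day is the percentage of stimuli answered with at least one beam
crossing. Two estimators exist:

- **fine** (bins no coarser than the 20-s inter-stimulus interval): each
  stimulus owns the response window up to the next stimulus; a window
  with any count is a hit.
- **coarse** (capped): per bin, `min(counts, stimuli in bin)` responses
  are credited and divided by the total stimulus count. This is the
  estimator used at the 1-min recording default, where individual 20-s
  response windows cannot be resolved.

The coarse estimator cannot exceed the fine one on response-like event
streams (at most one count per response window); with multiple counts per
window it can, which is why results always carry their mode label.
Success is averaged per fly over its living exercise days; the group
summary is the median and 25th/75th percentiles of fly means (Tukey
boxplot statistics). Exercise share relates window counts to the
morning + evening peak counts of the same day
(100 × window / (morning + evening)), excluding and flagging days with
zero peak activity.

## Group statistics

Two-sample comparisons default to the two-tailed Welch t-test (a pooled
variant is available by flag; Welch is the robust default since the
classical test's equal-variance assumption is rarely checked in practice)
and the Mann–Whitney U test (exact null for combined n ≤ 20 without ties,
normal approximation with tie correction above). Stars follow the usual
convention (* < 0.05, ** < 0.01, *** < 0.001); no multiple-testing
correction is applied, and reports say so. Quartiles use the
linear-interpolation convention; Tukey whiskers extend to the most
extreme points within 1.5 × IQR. Relative-to-control range summaries are
computed under two conventions — mean of per-day ratios, and ratio of
range-averaged means — because they differ whenever the control trend is
not flat; tables label which was used.

## The simulator

`simulate_fly` emulates what a DAM records from one fly, per minute:

- **Circadian intensity template** λ(ZT): baseline rate plus Gaussian
  morning and evening peaks (centers ZT0.5 and ZT11.5, width 0.8 h),
  multiplied by a siesta factor (ZT4–8, default 0.3) and a night factor
  (ZT12–24, default 0.2). Units: expected counts per wake minute.
- **Two-state wake/sleep process**: a minute-resolution Markov chain with
  phase-dependent exit probabilities 1 − exp(−f/μ), giving approximately
  exponential bout durations with means μ per phase (wake 60/15/10 min
  and sleep 15/40/90 min for day/siesta/night). The fragmentation factor
  f multiplies both exit rates: it shortens bouts without changing the
  wake/sleep balance, which is exactly the short-bout-share signature the
  fragmentation metrics measure.
- **Counts**: Poisson(λ × age) per wake minute, zero in sleep; the age
  modulation is a per-day multiplicative trend (base × decline^(day−1)).
- **Nocturnal spikes**: Poisson-many short forced wake bursts per night
  with elevated counts — the arrhythmic night-time spiking of the
  AD-like profile.
- **Exercise response**: on active days each of the 90 tube rotations
  independently elicits one beam crossing with probability `p_resp`,
  recorded in the stimulus minute. While the tube is rocking the
  mechanical perturbation dominates behavior, so the window counts on
  active days are the responses themselves rather than the spontaneous
  siesta process; this makes the planted `p_resp` recoverable by the
  capped estimator without bias.
- **Death**: a log-normal time parameterized by its median in days and a
  log-scale shape (default σ = 0.25, i.e. a ~25% coefficient of
  variation, typical of fly lifespan spread); the channel is silent
  afterwards. Exercising cohorts scale the median by
  `exercise_survival_factor`.

Each fly draws from a substream keyed by (experiment seed, group index,
channel), so output is fully deterministic and existing flies are
unchanged when cohorts are resized.

The four default profiles are loosely calibrated to the study groups this
emulates: response probabilities 0.3862 / 0.0944 / 0.4176 / 0.4814 and
non-exercising median survivals 40 / 27 / 35 / 21.5 days for the
wild-type-, driver-, reporter- and AD-like profiles, with the AD-like
exercising median at 28.5 days. The AD-like profile adds fragmentation
2.2, eight nocturnal spikes per night, 1.25× early activity and a steeper
age decline (0.93/day), reproducing early hyperactivity followed by a
late decline and an elevated short-bout share.

What the simulator does **not** model: post-exercise rest compensation
and sleep redistribution (unless planted explicitly through profile
deltas), overdispersed counts, social or positional effects within the
monitor, gradual morbidity before death (death is abrupt), and any
mechanistic circadian oscillator. Passing recovery tests therefore shows
the pipeline measures what the generator planted under realistic count
statistics — not that it would be unbiased against every pathology of
real recordings.

## Problem sizes and runtime choices

Parameter-recovery checks use the study's cohort geometry: 32 flies per
group, 12 exercise days for success recovery, and a 40-day recording for
survival recovery (long enough that nearly every fly with a 21.5-day
median dies on camera). The analysis drivers simulate 8 cohorts × 32
flies; the test suite uses smaller cohorts for property checks where the
property does not depend on n. Expected sampling spread at this geometry:
the group median of per-fly success (1,080 Bernoulli trials per fly) has
an SE of ~0.4 points; the 32-fly KM median with σ = 0.25 has an SE of
~1.2 days.

## Known limitations

- 1-min DAM files cannot resolve individual 20-s response windows; the
  capped estimator is this package's construction and is labeled as such.
- Day 1 of a recording that starts at ZT0 has a morning episode missing
  its pre-ZT0 portion (see above); the final recorded day donates its
  ZT20–24 bins to a (dropped) incomplete next day.
- The death call places death at the last observed movement, which
  precedes biological death by the fly's final rest bout; at realistic
  activity levels this bias is minutes, not days.
- With no censoring the KM median convention (smallest t with
  S(t) ≤ 0.5) can sit one event early relative to conventions that
  interpolate between the two middle order statistics.
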