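# Methods

## The analysis problem

Closed-system electronic nicotine delivery systems (ENDS) are not used in
discrete, self-terminating units the way cigarettes are: a user may take a
few puffs, put the device down for minutes or hours, and return to it many
times a day.  In-line logging hardware placed between the device battery
and cartridge records every puff — start time, duration, battery voltage
and current — over a multi-week ambulatory period, but turns the question
of "how is the product used?" into a segmentation problem: which puffs
belong together in a *use session*, and which gaps separate sessions or
represent nonuse?

`pufftop` implements an operational answer built from three rules applied
per participant, followed by end-point aggregation, cohort stratification
and between-group testing.

## The pipeline model

### 1. False-puff removal

Connecting or disconnecting the charger produces spurious sub-half-second
records at low voltage.  A record is removed iff

    duration < 0.5 s  AND  voltage < 3.3 V,

where 3.3 V is the activated product voltage of the device studied.  The
rule is a conjunction: a long low-voltage record or a short full-voltage
record is kept.  Both thresholds and a disjunctive variant (for
sensitivity analysis) live in `CleansingConfig`.  Removal is idempotent
and conserves counts (`removed + kept = in`), which the test suite asserts
on random and adversarial inputs.

### 2. Interpuff intervals and prolonged nonuse

The interpuff interval (IPI) runs from the *end* of one puff to the
*start* of the next, computed on the cleansed series.  Overnight breaks
(roughly 12–16 h) would otherwise dominate any IPI average, so IPIs
strictly greater than the participant's 95th-percentile IPI are flagged
as nonuse (`nonuse_mode="percentile"`, linear-interpolation quantile,
single pass, per participant).  An absolute mode (default 12 h) is
provided because a 95th percentile of a dense IPI series can sit far
below a true overnight gap; the percentile mode remains the default as it
matches the operational definition this package implements.  Flagging
affects only the IPI signal — the puffs flanking a flagged gap are kept.

### 3. Sessionization at the mean IPI

The participant's *mean IPI* — the arithmetic mean of non-flagged IPIs,
computed once over the whole evaluation period — is an adaptive
threshold.  Scanning in time order, an IPI closes the current session iff
it **strictly exceeds** the mean IPI or is a flagged nonuse gap.
Threshold-exceeding gaps become intersession intervals (ISIs); nonuse
gaps close sessions but are excluded from ISI statistics (reported ISI
means are minutes, not overnight hours).  Consequences of the strict
inequality: a stream whose IPIs are all equal forms exactly one session,
and a two-puff stream is always one session.  Single-puff sessions are
legal.  Session count is non-increasing in the threshold, which is
property-tested.

Open choices fixed here (the operational definition leaves them
unstated): the threshold is computed per participant (not pooled), in a
single pass (no recomputation after ISI extraction), and a session never
spans a nonuse gap.

### 4. End points

Seven participant-level end points: daily puffs, daily sessions, mean
session length (s), mean within-session IPI (s), mean puffs per session,
mean puff duration (s), mean ISI (min).  Aggregation is
session-then-participant: each session contributes its own mean with
equal weight (a puff-weighted pooling variant is available via
`weighting="puff"`).  Daily rates divide by the fixed evaluation period
(default 14 days), not days-with-use.  Sessions with one puff contribute
no within-session IPI.  Reported group SDs are between-participant SDs of
the participant means; pooled-session SDs would generally be larger for
the skewed end points.

### 5. Use groups and statistics

Participants with fewer than 10 total puffs over the evaluation period
are excluded, then percentile ranks of mean daily puffs are computed over
the remaining cohort (linear interpolation: min → 0, max → 100, ties get
their average rank; a nearest-rank estimator is available).  Bins are
left-closed/right-open — low [10, 40), moderate [40, 70), high ≥ 70 —
and ranks below 10 fall to low, a case the exclusion rule leaves empty in
cohorts like the original.

Each end point is compared with a one-way fixed-effects ANOVA (α = .05)
and Bonferroni post hoc: pairwise two-sided t tests on the pooled
within-group variance (df = N − k), raw p multiplied by the number of
pairs and capped at 1.  Product Evaluation Scale (PES) responses — 21
seven-point Likert items averaged into five domains (satisfaction,
psychological reward, aversion, comfort and ease of use, relief) — are
compared with two-sided pooled-variance t tests at α = .016 (strict
inequality at the boundary); Welch's correction is available by flag.
The bundled 21-item → domain mapping is a synthetic placeholder with the
conventional domain sizes (3/5/4/7/2); the instrument's true assignment
is not public, so studies using real PES data must supply their own
`pes_mapping.yaml`.

## Study-design module

For a normal mean with unknown SD, the two-sided CI half-width
t·S/√n is random through S.  With true SD σ,
P(half-width ≤ h) = F_{χ²,n−1}( (n−1)·(h√n / (t_{1−α/2,n−1}·σ))² ),
and `precision_sample_size` returns the smallest n reaching the required
width probability.  Two conventions matter and are deliberate:

* the half-width uses the t critical value with the *sample* SD (not z
  with the assumed SD) — under the planning inputs σ = 1.75 s,
  h = 0.5 s, 95% CI, width probability 0.9 this gives n = 61, with
  n = 60 failing (0.884 vs 0.904);
* the "overall" probability multiplies coverage by width probability
  (0.95 × 0.9 = 85.5%) as if independent; the exact joint probability
  differs slightly, but the product is the reporting convention.

The probability is *not* monotone in n at very small n (it dips until
n ≈ 11 before rising to 1), so the minimal-n search is a plain upward
scan rather than bisection; minimality is certified by evaluating n − 1.
A Monte-Carlo simulator of the half-width distribution provides an
independent cross-check.  Attrition inflation is the smallest r with
r(1 − a) ≥ completers (60 completers at 20% attrition → recruit 75).

## Synthetic-data generator

No raw participant streams from any real deployment are available, so
every pipeline stage is exercised against a generator with known ground
truth.  Its structure, per participant per day:

* an overnight gap U(12, 16) h defines a waking window opening at 07:00
  (window length 24 h − gap, i.e. 8–12 h);
* sessions per day ~ Poisson(mean); puffs per session ~ 1 + Poisson(mean
  − 1); the compound expectation days × sessions/day × puffs/session is
  verified against simulation;
* within-session IPIs and puff durations are truncated lognormals
  (bounds mean ± 4 SD, lower-clipped at 1 ms).  The underlying (μ, σ)
  are root-found so the *truncated* mean and SD equal the requested
  values exactly (closed-form truncated moments, 2-D Newton-type solve);
  recovery tests therefore compare against the preset value itself with
  no truncation-bias allowance;
* intersession gaps are lognormal with CV 0.5 around the requested ISI
  mean, hard-floored at `isi_min_s` (default: 2 × the within-IPI upper
  truncation bound, so true ISIs always dominate true within-IPIs).
  When a day's drawn schedule would overrun the waking window, gaps are
  compressed proportionally toward the floor.  This is the key
  concession to realisability: the published group-level means are means
  of per-participant ratios and are not jointly consistent (e.g. ~31
  sessions/day × 94 min mean ISI exceeds 24 h), so the generator
  honours session counts, puffs/session, within-IPI and duration
  moments exactly and lets daily puff totals and ISI means emerge;
* charger artifacts ~ Poisson(2/day), placed inside overnight gaps with
  duration U(0.05, 0.45) s and voltage 0 — exactly the records the
  false-puff rule removes, which is asserted record-for-record;
* genuine puffs log 3.3 V and a nominal 1.0 A.

Ground truth records each puff's session index (−1 for artifacts), each
interval's class (within-session / intersession / nonuse / artifact) and
each session's day.  Seeding: participant i of a study with master seed
s draws from `SeedSequence([s, i])`, so streams are reproducible
independently of cohort composition.

Two presets ship: **table2**, whose per-group means/SDs are the published
low/moderate/high topography values with the observed 12/24/19 cohort
split, and **separable**, a single-group regime (within-IPI ≤ 40 s,
ISI ≥ 400 s) in which the mean-IPI threshold provably falls between the
largest within-IPI and the smallest ISI, so segmentation must recover
ground truth exactly — asserted for every one of 50 seeds.

What the generator does *not* emulate: between-participant heterogeneity
within a group (all participants of a group share one parameter set, so
between-participant SDs are pure sampling noise and group SDs are much
smaller than published ones), day-of-week or time-of-day intensity
structure beyond the waking window, autocorrelation between consecutive
sessions, device clock drift, and missing-data/upload artifacts.  Passing
recovery tests therefore demonstrates correctness of the *pipeline
algebra* under the stated point-process model, not fidelity of any real
population's behaviour; in particular the published between-group
P values are not reproducible from synthetic data and are not targeted.

## Problem sizes and tolerances

Test-suite scales, chosen as the smallest sizes that make the stochastic
assertions sharp: oracle-equivalence suites run 1000 random instances per
operation (exact agreement for segmentation/flagging/ranks, ≤ 1e-10
relative for the ANOVA F); ground-truth recovery runs 50 seeds × 14 days
of the separable preset; parameter recovery runs 50 seeds of the full
55-participant, 14-day table2 cohort, asserting group-mean puff duration
within 3 Monte-Carlo SEs of the generative mean and the qualitative
orderings (high > moderate > low daily puffs; moderate sessions shortest)
in ≥ 45/50 seeds.  The whole suite completes in well under a minute on
one CPU.  Numerical conventions: strict inequalities at the session
threshold, the nonuse quantile and the PES α; linear-interpolation
quantiles and percentile ranks throughout; NaN (never 0) for undefined
means; p values displayed as three decimals floored at "<.001".

## Known limitations

* The nonuse 95th-percentile rule interacts with use intensity: for a
  heavy user it can flag large genuine ISIs (excluding them from the
  threshold mean), and for the heaviest simulated group the threshold can
  fall slightly below the within-IPI truncation bound, occasionally
  splitting true sessions.  Both behaviours are inherent to the
  operational definition, not implementation artifacts.
* `GroupComparison` reports both raw and Bonferroni-adjusted pairwise p
  values; which convention a published table used cannot generally be
  recovered without raw data.
* The CLI's `compare` output is one row per end point; it does not
  attempt journal-style table formatting beyond `format_p_value`.
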