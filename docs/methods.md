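# Methods

This note records the model underlying `digiphen`, the conventions the
implementation fixes where the underlying study protocol is silent, and
what the synthetic cohort does and does not establish.

## Time and windowing

All timestamps are stored in UTC with a per-subject IANA timezone;
every day/night decision is made in local civil time, since clinical
days are local.  The *day* window of date D is [D 07:00, D 23:00) and
the *night* window is [D 23:00, D+1 07:00); the night starting at 23:00
on D belongs to D.  Both windows are half-open, so the pair tiles the
clock and no sample is ever double-counted.  The same attribution rule
is used for every stream — steps, GPS, calls, SMS, light and screen —
so "a subject-day" means the same 24 hours everywhere.

## Mobility

**Speeds.**  The speed at fix *k* is the WGS84 geodesic distance from
fix *k−1* divided by the elapsed time; the first fix of a trace
inherits its successor's speed.  Gaps longer than 5 minutes split the
trace: no speed, distance or dwell is carried across a gap, and a
single isolated fix has undefined speed.  Fixes are *stationary* below
0.2 m/s and *in transition* at or above 1 m/s.  The band [0.2, 1) m/s
is deliberately left as a third state, *ambiguous*, excluded from both
place clustering and transition time — the two defining thresholds say
nothing about it, and folding it into either state would bias dwell or
travel time.

**Geodesics.**  Distances use Vincenty's inverse formula on the WGS84
ellipsoid (vectorized; sub-millimetre agreement with an independent
Karney-style implementation on random pairs — see the frozen reference
table under `tests/data/`).  Vincenty's iteration stalls for nearly
antipodal pairs; those fall back to the Lambert/Andoyer closed form
(~10 m error), which is irrelevant at daily-mobility scales but keeps
the function total.  With `fallback=False` non-convergence raises
rather than returning a silent NaN.

**Places.**  Stationary fixes from the *whole study period* are
clustered per subject by K-means with K grown from 1 until every fix
lies within 500 m (geodesic) of its assigned centre.  Lloyd iterations
run on a local equirectangular projection — averaging raw lat/lon
degenerates away from the equator — while the 500 m coverage check is
always geodesic.  The inner K-means is seeded (k-means++, several
restarts), making the whole procedure deterministic under a fixed seed.

**Daily features.**
- *location variance* = ln(var lat + var lon) over the day's stationary
  fixes, variances in degrees² and natural log (the definition operates
  on raw coordinates; users comparing cohorts across latitudes should
  note a degree of longitude shrinks with latitude).  When the sum
  underflows (a single point), the value is floored at ln(1e−12).
- *normalized entropy* = −Σ pᵢ ln pᵢ / ln N, where pᵢ are the day's
  dwell-time fractions over the places visited that day and N is the
  study-wide cluster count.  Dwell time per stationary fix is the gap
  to the next fix within the same trace segment.  The value is 0 for a
  single-place day and undefined (missing) when the study has only one
  cluster, since ln 1 = 0.  The ratio of logarithms makes the measure
  base-invariant and confined to [0, 1].
- *home stay*: the protocol lists home stay but never defines "home".
  Convention here: home is the cluster holding the largest share of
  study-wide night-window stationary dwell; home stay is the day's
  dwell fraction in that cluster.  This is an extension, flagged as
  such.
- *visited places*: clusters touched by at least one stationary fix
  that day; no minimum-dwell requirement (also a convention).
- day totals of distance attribute each inter-fix hop to the later
  fix's date; transition segments are attributed to their start date.

## Social features

Calls and SMS are ranked separately into study-wide top-10 contact
lists ("most frequent" = record count; ties broken by total
duration/length, then hash, so the selection is order-invariant and
deterministic).  All daily statistics except `n_unique_call_partners`
are restricted to the top-10 set.  Missed calls count toward call
counts but are excluded from duration totals and means — the logs
record "missed" as a type without usage rules, so this is a declared
convention.  Incoming and outgoing records are pooled; direction is
retained in the data model for extensions.  Only MD5 hashes of
canonicalized identifiers (digits-only phone numbers, lower-cased
addresses) ever appear in outputs.

## Context features

Ambient light is averaged per local clock hour; a night hour (23:00–
07:00) with mean lux strictly below τ_I counts as dark, and the count
of dark night hours serves as a sleep-duration proxy.  τ_I defaults to
10 lux — the protocol calls the threshold empirical without printing
it, and 10 lux is a conventional indoor-darkness bound — and is
configurable.  Screen hours count hours whose 30-second on-fraction
strictly exceeds τ_S = 0.10.  Both inequalities are strict, exactly as
the thresholds are written.  Hours with no samples are *missing*, not
dark/off: sensor dropout must not look like sleep.

## Correlation protocol

Daily features are aggregated by the mean over the half-open window
(visit − 14 d, visit]; a feature with no non-missing day in the window
stays missing, and per-feature day counts are available for QC.  The
aggregation statistic is the mean rather than the sum, so compliance
gaps do not masquerade as behavioural change.  Observations are pooled
across subjects and visits into a single Pearson correlation per
(feature, score) pair — the study-scale n and figure structure imply
pooling, though within-subject correlation would control for stable
between-subject differences; this is documented as a pooled analysis.
Two-sided p-values come from the t distribution with n−2 df, starred at
p<.1 / p<.05 / p<.01 with no multiplicity correction (matching the
convention mirrored here); a Benjamini–Hochberg flag is available.

## Prediction

The split unit is the biweekly observation row (4:1, seeded).  Row
splits let a subject appear on both sides; `--split-by subject` closes
that leak at the cost of a noisier estimate with few subjects, and the
default is documented honestly as the more optimistic protocol.  Models
are ordinary least squares and an SVR with polynomial kernel of degree
3 with sklearn defaults (C = 1, ε = 0.1) — nothing beyond "polynomial
kernel" is prescribed.  Median imputation and standardisation are fitted
on the training rows only, inside one sklearn `Pipeline`.  Predictions
are clipped to the PHQ-9 range [0, 27].  The *variance score* is the
test-set coefficient of determination 1 − SS_res/SS_tot — the only
standard score that is ≤ 1 and can be negative, as required by the
result layout it mirrors; it is undefined (missing) for a constant test
target.  `accuracy = 100 × (27 − RMSE)/27` rescales the error by the
instrument range.  A single seeded split is the default; repeated
splits can be run by looping seeds.

## Synthetic cohort

The generator defines the study conditions under which every test
runs: an 8-week cohort of families in one metropolitan timezone, teen
compliance 0.79 and parent compliance 0.957 (the reported adherence
rates), and a latent daily severity s_d per teen — a Gaussian random
walk (step SD 0.4/day) clipped to [0, 27], started from N(12.72, 5.97),
the reported cohort PHQ-9 distribution.

Channels are generated conditionally on s_d:

- **steps**: hourly Poisson counts with log-linear rate
  `(7000/16)·exp(β_steps·s)`, β_steps = −0.025, day-level lognormal
  noise (SD 0.3 on the log scale); small severity-independent night
  counts.
- **GPS**: 12 anchor places per subject — home plus a ring at 1–6 km —
  sampled every 5 min while stationary (1 min in transit), with 5 m
  jitter.  The day's place count is log-linear in s (β_places = −0.03
  about a baseline of 8), away-places are selected with probability
  ∝ exp(β_locvar·s·d_km) (β_locvar = −0.06), pulling activity toward
  home at high severity, and dwell across the visit sequence decays
  geometrically with ratio 0.35 + β_entropy·s (β_entropy = +0.02), so
  higher severity spreads time more *uniformly* across the (fewer)
  visited places.  The uniformity effect is set strong enough to
  dominate the entropy cap imposed by the shrinking place count —
  fewer places and higher normalized entropy are simultaneously
  plantable, matching the observed direction pattern.  Nights are
  spent at home, which also grounds the home-stay definition.
- **calls/SMS**: a 15-contact pool with Zipf-like weights (so top-10
  selection is non-trivial); call durations lognormal with log-mean
  `ln 240 + β_call_duration·s` (β = −0.035), SMS counts Poisson with
  rate `25·exp(β_sms_count·s)` (β = −0.05); 10% of calls are missed
  (duration 0).
- **EMA**: teen mood = clip(100 − 3s + N(0, 8)), anxiety similar; the
  parent-about-teen report adds N(0, 10) observer noise on top of the
  teen's value.  Higher slider = better state; the linkage sign is a
  generator convention, since only correlation magnitudes are reported
  for this channel in the literature it mirrors.
- **light/screen**: diurnal profiles with per-hour randomness,
  generated *independently of s* — planted nulls used to check the
  false-positive rate of the correlation stage.
- **assessments**: every 14 days; PHQ-9 = round(mean s over the
  trailing fortnight + N(0, 1)), HAM-D and HAM-A are monotone noisy
  transforms (×1.7 and ×1.5) of the same window mean, clipped to their
  ranges.

Zero effect sizes are allowed (planting a null); a sign-violating
configuration is refused at validation time.  Each (seed, subject,
channel) triple seeds an independent generator, so cohorts are
bit-reproducible and extensible.

A second, deliberately minimal generator
(`simulate_linear_observations`) bypasses the sensor layer entirely:
features affine in a latent severity with standardized measurement
noise, and PHQ-9 = severity + N(0, σ).  It exists to check parameter
recovery — the regression stage must return a test RMSE near σ, and a
non-positive variance score when the features carry no signal.

**What the synthetic cohort does not show.**  Real streams have duty-
cycle artifacts, clock skew, duplicate rows, urban-canyon GPS noise,
missingness correlated with symptom severity, and between-subject
heterogeneity in baseline behaviour — none of which are emulated (GPS
is also generated at a 5-minute stationary cadence rather than the
seconds-scale logging of a displacement-triggered logger, purely to
keep simulated cohorts tractable).  Correlation magnitudes and
prediction errors on synthetic cohorts are therefore cleaner than any
real deployment would produce; the test suite asserts *directions*,
*coverage properties* and *recovery of planted scales*, never the
magnitudes reported from clinical cohorts, whose raw data are not
available for comparison.

## Problem sizes and numerical choices

The acceptance suite runs a 50-family cohort for sign recovery (200
biweekly observations), 20 replicate 12-family cohorts for the null-
rate check, 1,000 fuzzed point sets for clustering coverage, and a
100-family linear cohort for parameter recovery — sizes chosen so the
planted effects are unambiguous at desk scale.  The null-rate bound
(≤ 12.5% of null-channel correlations at p<.05, nominal 5%) allows for
the strong dependence among the three psychometric scores, which makes
the nine tests per cohort far from independent.  Ties in k-means are
resolved by seeded restarts keeping the best inertia; entropy
renormalises dwell within the day; all floors, clips and undefined-value
contracts are stated alongside the formulas above.

## Known limitations

- Home detection assumes nights are spent at the modal night location;
  shift workers would need a different rule.
- Location variance in degrees² is latitude-dependent across cohorts.
- Pooled correlations conflate within- and between-subject effects.
- Row-level train/test splits share subjects across the split (see
  above); subject-level splitting is available but noisy at small n.
- The polynomial SVR uses fixed default hyperparameters; no search is
  performed.
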