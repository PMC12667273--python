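# Methods

## Problem and scope

`somnarc` estimates the nightly *major sleep episode* — onset, wake
time and duration — from week-long raw wrist accelerometry, applies
cohort-level quality control, and computes age- by sex-stratified
statistics of the detected sleep parameters: group means with standard
errors, weekday/weekend contrasts, polynomial age trends, Cohen's d
effect sizes, and associations with self-reported sleep and mood items.
Because the population data such analyses target cannot be
redistributed, the package ships a synthetic cohort generator with
known ground truth; every claim the pipeline makes is validated by
parameter recovery against that truth.

## Detection model

The detector makes one behavioural assumption: sleep is the longest
sustained run of low within-person movement in each noon-to-noon
window. It estimates it in seven stages.

1. **Resampling.** The raw tri-axial stream is linearly interpolated
   onto an exact 20 Hz grid. Gaps wider than 1 s are flagged and never
   interpolated across.
2. **Non-wear.** Per minute, the within-minute SD of each axis is
   averaged across axes; a minute is off-wrist when its forward *or*
   backward 150-min mean of that SD falls below 0.004 g. The one-sided
   rule lets a detected non-wear interval cover the full low-variance
   span rather than only its core. The threshold sits between the
   residual noise of an unworn device (~1e-4 g here) and the stillest
   sleep (~0.005 g per axis); it is configurable and would need
   re-tuning for hardware with a different noise floor.
3. **Activity power.** Per minute and axis the mean is removed, the
   periodogram computed and its area integrated; the minute's power is
   the root of the summed axis integrals. By Parseval's theorem this
   equals the RMS of the mean-removed signal — the test suite asserts
   the agreement within 1% — so the spectral path and a direct RMS are
   interchangeable cross-checks.
4. **Percentile scoring.** Worn minutes are ranked within participant
   and labelled with the smallest grid percentile (5..100 by 5,
   nearest-rank thresholds) whose threshold covers their power. Ties
   take the lowest covering category. Everything downstream depends
   only on these ranks, making detection invariant to rescaling the
   input (the absolute non-wear threshold in stage 2 is the only
   scale-sensitive step).
5. **Smoothing.** Candidate sleep is seeded at categories at or below
   the 50th percentile and consolidated by three passes of
   forward/backward moving averages (100, 60, 90 min), each thresholded
   at 0.5, with off-wrist minutes forced non-sleep. The seed sits at
   the 50th rather than a lower percentile because an ~8 h episode
   occupies 30–35% of a 24 h record: a seed below the sleep fraction
   marks only part of the episode's minutes and the 0.5-thresholded
   averages then erase the night entirely. With the 50th-percentile
   seed every sleep-ranked minute seeds, and the passes remove
   scattered quiet wake minutes instead.
6. **Extraction.** Per noon-anchored night window, the longest
   candidate run whose midpoint falls inside the window becomes the raw
   episode; ties break toward the lower mean category, then the earlier
   run. Runs shorter than 30 min flag the night as having no detected
   sleep.
7. **Refinement.** Hierarchical rules adjust the raw episode:
   (i) *merge* — bouts of at least 30 min within a 30-min gap whose gap
   minutes all rank at or below the 25th percentile are absorbed, to a
   fixed point; (ii) *trim* — boundary minutes ranking above a trim
   threshold retract; (iii) *extend* — boundaries advance over adjacent
   minutes at or below the 10th percentile.

   The trim threshold adapts to the episode: it is the 0.9 quantile of
   the categories in the episode's core (middle 60%), clipped to
   [25th, 50th]. Rationale: minutes a smoothing pass wrongly attaches
   at the boundary (quiet pre-sleep wakefulness) always rank *above*
   every core sleep minute, but where that rank falls on the fixed grid
   depends on the participant's sleep fraction; an episode-relative
   threshold removes them for any fraction, while a fixed 50th-percentile
   cut cannot. A boundary minute survives only if the median of the
   next few minutes inward also sits below the threshold, which makes
   the stopping rule robust both to isolated movement bursts inside
   sleep and to stray low-ranked wake minutes in the attached zone.

The four named decision percentiles (10/25/50/75) therefore act as:
extension bound (10th), merge-gap quietness bound (25th), seed and trim
ceiling (50th); the 75th marks the clearly-active band used in
reporting. All roles are configuration fields.

### Accuracy, empirically

On noise-free square-wave weeks the full 20 Hz pipeline recovers every
onset and wake exactly (the acceptance suite requires ≤ 2 min). Under
the generator's default noise the median absolute boundary error is
~4 min with a small systematic compression (onset late, wake early, by
the smoothing-erosion of the episode edges); the compression is
identical across strata and cancels in every contrast the analysis
reports. About 0.1% of simulated nights are drawn so short by nightly
noise that a long afternoon sedentary block is genuinely the longest
low-activity run and is selected instead — a faithful consequence of
the longest-run rule, kept rather than patched.

## Quality control

A participant fails QC with explicit reason codes when: the recording
is shorter than 7.5 days (`short_record`); any off-wrist minute falls
strictly within days 2–7, or an edge-day off-wrist interval clips a
detected episode (`midweek_wristoff`); more than 4 nights lack a
detected episode (`missing_days_gt4`); the recording spans a
daylight-saving transition of its timezone (`dst_overlap`); more than
20% of samples are gap-flagged or an axis stays flat for over 24 h
while worn (`structural_anomaly` — an explicit, automated stand-in for
manual structural review); or the id appears twice (`duplicate`; the
record with more detected nights, then the earlier start, survives).
The discovery/replication split is a seeded random halving stratified
by sex × age bin; each stratum's arms differ by at most one record, the
odd record going to the globally smaller arm (ties by a deterministic
hash of the participant id), so a cohort of 77 093 always splits
38 546/38 547.

## Statistical analysis

All group statistics aggregate to the participant level first (one mean
per participant per parameter); nights are never treated as independent
observations, so standard errors are across participants. Group
summaries report n, mean, SE = SD/√n, and percent of cohort (2
decimals). Weekday/weekend contrasts are within-participant differences
(weekend = Saturday/Sunday wake days by default; a flag switches the
attribution to onset days), averaged across participants and tested
with a paired t-test. Age trends are OLS polynomial fits (order 1 and
2) of group means on bin midpoints (46.5, 52, 57, 62, 67, 72, 78.5);
R² = 1 − RSS/TSS, and the nestedness R²(quad) ≥ R²(lin) is asserted on
every fitted series. Cohen's d uses the n−1-weighted pooled SD without
small-sample correction, with a normal-approximation 95% CI. Group
comparisons use Student's pooled-variance two-sample t (Welch behind a
flag, since the analysis convention named plain t-tests) and one-way
ANOVA with (k−1, N−k) df, at α = 0.05 per contrast with **no
multiple-testing correction** — mirroring the per-contrast convention
of the analyses this package reproduces; treat families of p-values
accordingly. The four-level depression and anhedonia items are
dichotomized as "not at all" → No, any other frequency → Yes.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are the
calibration the analyses are validated against.

**Schedules.** Baseline onset/wake tables per sex × age bin (minutes
past preceding noon) encode mildly quadratic age shapes with total
durations of 455–473 min. Under-60 male schedules start 9/17 of the
sex gap later and end 8/17 earlier (17 min shorter in total, the
calibrated effect); the gap halves in the 60–64 bin and vanishes from
65. Friday and Saturday nights gain the weekend shift (50 min of
duration, split +0.3·s onset and +1.3·s wake), tapering identically
with age. Person-level variation is a chronotype shift (SD 45 min)
moving onset and wake together plus an independent person-duration
offset (SD 10 min); nightly noise adds 30 min SD per boundary. The
chronotype formulation keeps between-person duration variance small,
which is both the field-standard view of stable individual timing and
what gives the recovered sex gap a ~1 min sampling SE at 1000/sex. No
published variance components exist for these quantities; they are free
parameters of the emulation.

**Signal.** Raw samples are the gravity vector plus white noise whose
per-axis SD follows a diurnal profile: morning peak 0.10 g, midday
0.08 g, a flat sedentary block 12:30–17:30 at 0.030 g, evening decline
to a flat 0.050 g plateau from 22:00 through the night. Sleep minutes
drop to 0.005 g with sparse movement bursts (5% of minutes, 0.05–0.15 g);
off-wrist segments are near-constant (1e-4 g). Two profile features are
deliberate: the *flat* pre-onset plateau makes the signal context at
sleep onset independent of chronotype (a declining profile would make
detection error covary with schedule timing and bias sex contrasts),
and the afternoon block — the quietest waking period — anchors the
middle of the within-person rank distribution so that the
50th-percentile seed cuts through it, far from the night episode, for
any realistic sleep fraction. Both were fixed from this rank-composition
analysis at design time. The per-minute fast path draws each minute's
power directly from the RMS sampling law
`power² = σ²·χ²(3m−3)/m` (m samples/minute), which is exactly the
statistic the 20 Hz path integrates; the equivalence is tested. A
`square_wave` mode replaces the diurnal profile and bursts with two
flat levels (deterministic equal-power sines plus 1% jitter) for
noise-free recovery tests.

**Self-reports.** Reported hours = round(2.0·true_hours − 8.0 + ε),
ε ~ N(0, 0.8 h), clipped to [3, 12]: the expansion factor 2 maps a
~1.5 h objective spread onto a ~3 h reported spread, emulating the
compression of objective relative to self-reported differences.
"Waking too early" is a logistic function of earlier chronotype;
"sleeping too much" of later chronotype and lower activity — so both
shift timing without shifting duration, as observed. Depression
(baseline prevalence 15%, a free parameter) loads on later chronotype,
lower activity and shorter person-duration; anhedonia shares the latent
flag with 5% discordance. Directions follow the reported associations;
magnitudes are free parameters, and a `zeroed()` variant supports
type-I-error calibration.

**What the generator does not emulate** — and hence what passing tests
cannot show about real data: postural gravity shifts and device
calibration error, naps and fragmented sleep, within-night wakefulness,
heteroscedastic or autocorrelated movement noise, device temperature
effects, and any non-wear pattern beyond constant-signal segments.
Detection accuracy on real recordings must be validated against
polysomnography or annotated actigraphy, not inferred from these
simulations.

## Numerical choices and degenerate inputs

Nearest-rank percentiles use exact integer arithmetic
(`ceil(p·n/100)`), avoiding float boundary errors; ties take the lowest
covering category, so an all-constant power series scores category 5
everywhere. Scoring requires ≥ 1440 worn minutes, otherwise the
participant is rejected with a reason code. Sleep-table CSVs are
re-read with correctly-rounded float parsing so durations round-trip
bit-exactly. If refinement collapses an episode below 30 min the raw
episode is kept and flagged rather than dropped. Runs at the window
boundary belong to the window containing their midpoint, so an episode
is never attributed to two nights.

## Problem sizes

The recovery analyses use 1002 participants per sex (334 per under-60
age bin × 3 bins), simulated at minute resolution — the level at which
all detection logic past the power integration operates — with the raw
20 Hz path exercised on single-participant fixtures where its extra
fidelity matters (resampling, non-wear, spectral integration). Type-I
calibration uses 500 replicates of 20–24 participants per arm at truth
level. These sizes give sampling SEs several times smaller than the
recovery tolerances (±3 min on the 17-min gap, ±5 min on the 50-min
weekend shift).

## Known limitations

* The non-wear threshold is absolute (g units); detection as a whole is
  scale-invariant only above it.
* The longest-run rule can select a long sedentary block on nights with
  extreme schedule noise (~0.1% of simulated nights).
* Onset/wake carry a systematic ~4-min inward compression under noise;
  absolute durations are accordingly conservative even though contrasts
  are unbiased.
* No correction for multiple comparisons anywhere.
* The discovery/replication split is provided, but the package does not
  itself enforce running analyses separately per arm.
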