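# Methods note

This document records the methodological conventions, the synthetic
generator's design, and the numerical choices behind `sedpatterns`.

## Measurement pipeline

### Epochs and vector magnitude

Input is one-minute epoch data with three axis counts per epoch. Vector
magnitude (vm) is the Euclidean norm of the three axis counts and is the
series all detection and classification operates on. Epoch series must be
contiguous at 60-second spacing; validation names the first offending row.

### Nonwear detection

An epoch is nonwear if it lies in any *qualifying window*: a window of ≥90
consecutive minutes whose counts are zero except for at most 2 nonzero
"spike" minutes, each of which is flanked by ≥30 zero minutes on both sides
(all flanking minutes inside the window). The flag set is the union of all
qualifying windows — a Choi-type rule.

Implementation note: a qualifying window must start and end on zero epochs
(a boundary spike cannot be flanked), so the search space reduces to windows
aligned with maximal zero runs. The detector walks zero runs and extends each
candidate rightwards while the spike budget and flank conditions hold; this
is equivalent to full window enumeration (the test suite proves equality
against a literal enumeration reference) but linear in the number of runs.

### Sleep exclusion and wear time

Diary bed→wake windows are flagged as sleep. Wear time for a calendar day is
`1440 − |sleep ∪ nonwear|` minutes: overlap between sleep and detected
nonwear is counted once. Interior days without both a bed and a wake diary
record are recorded as diary-uncovered.

### Valid days and retention

Days are calendar days (midnight to midnight). The first and last recording
days are dropped as partial. A day is valid when waking wear time is ≥10 h
and the diary covers it. A participant is retained when ≥7 *consecutive*
valid days exist; the first such run of 7 is used for analysis. Exact
boundaries are inclusive: exactly 10.0 h and exactly 7 valid days retain.

### Intensity classification and bouts

Only wear epochs on valid days are classified, using vm cut points:
sedentary <200 cpm, light 200–2689, moderate 2690–6166, vigorous ≥6167
(configurable). A sedentary bout is a maximal run of sedentary epochs,
broken at midnight so bouts never straddle days.

### Pattern metrics

Per participant, over the valid days, with L ∈ {10, 20, 30, 60} minutes:

- `st_minutes_per_day`, `st_minutes_per_week = 7 × ST / valid days`;
- `pct_st_in_bouts_L = 100 × (Σ durations of bouts ≥ L) / total ST`;
- `bouts_per_sed_hour_L = (# bouts ≥ L) / (ST in hours)` and
  `bouts_per_week_L = 7 × (# bouts ≥ L) / valid days` — both frequency
  normalizations are emitted because both appear in the literature and they
  answer different questions (density within sedentary time vs. weekly rate);
- `mean_bout_duration_30`: mean duration of bouts ≥30 min, `NaN` when no such
  bout exists (a zero-ST participant likewise gets `NaN` ratios, with a
  machine-parsable warning logged).

These satisfy two identities used as acceptance checks: metrics are
non-increasing in L, and
`mean_bout_duration_30 = (pct_st_in_bouts_30/100 × st_minutes_per_week) /
bouts_per_week_30` holds exactly per participant.

## Association analysis

### Regression

Each SF-36 domain or summary score is regressed (OLS) on one pattern
exposure plus a covariate family:

- `base`: age, body fat %, occupational status, analgesic use,
  antidepressant use, wear minutes per day;
- `base_mvpa`: base + MVPA minutes per day;
- `base_st`: base + total sedentary minutes per week (for bout-frequency
  exposures);
- `base_st_mvpa`: base + both.

Reported per cell: unstandardized B, SE, standardized
`beta = B × sd(exposure)/sd(outcome)` (sample SDs of the complete-case
analysis sample), p, and t-based 95% CI. Missing data are handled by
listwise deletion. Rank-deficient designs raise an error naming the
collinear columns (via pivoted QR); in the model grid such cells are flagged
and the rest of the grid is unaffected. No multiple-testing correction is
applied; the outputs carry the number of tests run so readers can adjust.

### Median splits and ANCOVA

Participants are split at the sample medians of `st_minutes_per_week` and
`mean_bout_duration_30` (ties go to the low group), giving four joint groups
(`low_low` … `high_high`). Participants with no prolonged bout have an
undefined mean bout duration; by default they enter with duration 0 (hence
"low") and are counted, with an option to exclude them instead — the choice
is surfaced because published analyses rarely state it.

ANCOVA is OLS with three group indicators (reference `low_low`) plus the
base covariates (optionally MVPA). Adjusted means are model predictions at
the sample covariate means; all six pairwise contrasts carry t-based 95% CIs
and p-values, unadjusted for multiplicity.

## Synthetic generator

The generator emulates the *data-generating process the pipeline assumes*,
so that every stage has exact ground truth:

- **Sleep schedule**: per-participant bed/wake times, normally jittered
  around 23:00/07:30 (SD 20 min), drawn per day.
- **Waking behaviour**: an alternating renewal process of sedentary and
  active bouts. Sedentary durations are lognormal (μ=1.085, σ=1.235 on the
  log scale), calibrated numerically (least squares on the lognormal tail
  formula) so that the long-run occupancy of sedentary time in bouts
  ≥10/20/30/60 min is ≈59/38/27/10 % — the heavy-tailed profile reported for
  sedentary accumulation in low-active clinical cohorts, under which the
  mean prolonged-bout duration is ≈48–54 min. Active bouts are
  exponential (mean 7 min). Durations are discretized by ceiling to ≥1 min.
- **Counts**: sedentary epochs draw counts uniformly in [1, 199]; active
  epochs draw from a lognormal intensity distribution clipped to
  [200, 50000] cpm. Zero counts
  are *reserved* for sleep and nonwear, so zero runs identify them exactly.
- **Nonwear**: Poisson-injected waking episodes of ≥90 min. Each episode
  either touches a waking-window edge or keeps ≥3 min of activity
  (`NONWEAR_BUFFER_MINUTES`, one more than the default spike tolerance)
  between itself and any adjacent zero region; otherwise a spike-tolerant
  detector would bridge a 1–2-min activity gap into the surrounding sleep
  zeros and flag waking minutes, breaking exact recoverability.
- **Covariates and outcomes**: age and body fat % are truncated normals;
  binary covariates are Bernoulli. SF-36 scores follow a configurable linear
  model on the participant's *true* pattern metrics and covariates plus
  Gaussian noise, clamped to [0, 100] — so effect-recovery and calibration
  studies know the generating coefficients.

Ground truth per participant: per-epoch labels (sleep/nonwear/sedentary/
active), the true bout list broken at midnight, and true wear per day.
`truth_pattern_summary` recomputes the pattern metrics from labels alone and
serves as an independent oracle; on generated data the pipeline reproduces
it exactly on the analysis days.

What the generator does **not** emulate: device noise on nonwear/sleep
epochs (zeros are exact), within-person day-of-week structure, diary errors,
or missing data. These are deliberate: the generator's purpose is validation
with exact ground truth, not realism beyond the marginal distributions.

For replicated simulation studies (type-I error, CI coverage),
`generate_analysis_table` draws participant-level metric/covariate tables
directly from marginal distributions — no epoch simulation — keeping 400-fit
calibration studies in seconds.

### Determinism

Every participant draws from `numpy` `SeedSequence`s spawned from the cohort
seed and the participant id (separate streams for schedule, activity,
covariates, outcomes), so cohorts are reproducible participant-by-participant
and independent of generation order. Pipeline runs with the same config and
seed are byte-identical; the manifest's `config_hash` (SHA-256 of the
canonical config, excluding the output directory) identifies the scientific
configuration.

## Numerical choices

- OLS via `statsmodels`; standardized beta and CIs computed from the fitted
  exposure term with `t(n−k−1)` quantiles.
- Rank checks via pivoted QR so error messages can name offending columns.
- Oracle comparisons in the tests use 1e-8 (regression/ANCOVA algebra),
  1e-10 (noise-free recovery), 1e-12 relative (summary arithmetic), and
  exact equality for flags, bout lists, counts, and retention decisions.
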