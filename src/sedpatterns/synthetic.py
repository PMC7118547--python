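"""Synthetic cohort generator with known ground truth.

Free-living activity is emulated as an alternating renewal process: within
each waking window, sedentary bouts (heavy-tailed lognormal durations, counts
below the sedentary cut point) strictly alternate with active bouts (counts at
or above it). Diary sleep and injected nonwear windows overwrite counts with
zeros. Because the generator records per-epoch truth labels, the true bout
list, and the true outcome-model coefficients, every downstream stage can be
checked against an oracle that never touches the detection code.

Two deliberate conventions keep truth attribution unambiguous:

* sedentary wear epochs draw counts in [1, 199] — the zero count is reserved
  for sleep and nonwear, so sustained-zero nonwear detection can never
  swallow genuinely worn epochs;
* injected nonwear episodes always span at least the detector's minimum run
  length, so true nonwear is always detectable.

Long-run behaviour follows renewal-reward logic: the fraction of waking time
spent sedentary converges to E[sed bout] / (E[sed bout] + E[active bout]).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distributions import Dist, duration_minutes
from .errors import ConfigError
from .io import (
    COVARIATE_COLUMNS,
    SF36_ALL,
    EpochSeries,
    SleepDiary,
    _empty_flags,
    compute_vector_magnitude,
)

MINUTES_PER_DAY = 1440


def default_outcome_model() -> dict:
    """Linear outcome model per SF-36 score: intercept, coefficients, noise SD.

    Coefficient predictors may name any pattern metric or covariate. The
    defaults encode moderate negative dependence of the physically loaded
    scores on the share of sedentary time accumulated in prolonged bouts,
    with intercepts placed so cohort means land in a realistic band.
    """
    return {
        "physical_function": {"intercept": 55.0, "coef": {"pct_st_in_bouts_30": -0.25, "age": -0.15, "body_fat_pct": -0.10}, "noise_sd": 15.0},
        "physical_role": {"intercept": 40.0, "coef": {"pct_st_in_bouts_60": -0.24}, "noise_sd": 19.0},
        "bodily_pain": {"intercept": 30.0, "coef": {"pct_st_in_bouts_30": -0.11}, "noise_sd": 13.0},
        "general_health": {"intercept": 29.0, "coef": {}, "noise_sd": 14.0},
        "vitality": {"intercept": 40.0, "coef": {"pct_st_in_bouts_30": -0.20, "body_fat_pct": -0.20}, "noise_sd": 15.0},
        "social_functioning": {"intercept": 60.0, "coef": {"pct_st_in_bouts_30": -0.35}, "noise_sd": 20.0},
        "emotional_role": {"intercept": 57.0, "coef": {}, "noise_sd": 25.0},
        "mental_health": {"intercept": 46.0, "coef": {}, "noise_sd": 18.0},
        "pcs": {"intercept": 33.0, "coef": {"pct_st_in_bouts_30": -0.09}, "noise_sd": 6.0},
        "mcs": {"intercept": 36.0, "coef": {}, "noise_sd": 10.0},
    }


@dataclass(frozen=True)
class SleepSchedule:
    """Mean bed/wake clock times (minutes after midnight) with nightly jitter."""

    bed_mean_minute: int = 1380  # 23:00
    wake_mean_minute: int = 450  # 07:30
    jitter_sd_minutes: float = 20.0

    def validate(self) -> None:
        if not (1260 <= self.bed_mean_minute <= 1435):
            raise ConfigError("bed_mean_minute must fall in the evening (21:00-23:55)")
        if not (240 <= self.wake_mean_minute <= 720):
            raise ConfigError("wake_mean_minute must fall in the morning (04:00-12:00)")
        if self.wake_mean_minute >= self.bed_mean_minute:
            raise ConfigError("impossible schedule: mean wake at/after mean bed time")
        if self.jitter_sd_minutes < 0:
            raise ConfigError("jitter_sd_minutes must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the synthetic cohort.

    The defaults emulate the study protocol: 9 recorded days of 1-minute
    epochs worn around the clock, diary-defined sleep of roughly 8.5 h,
    occasional daytime nonwear, and a sedentary bout-duration distribution
    whose heavy tail populates all four cumulative length categories with a
    decreasing occupancy profile.
    """

    n_participants: int = 407
    n_days: int = 9
    epoch_seconds: int = 60
    sedentary_bout_dist: Dist = field(
        default_factory=lambda: Dist("lognormal", {"mu": 1.085, "sigma": 1.235})
    )
    active_bout_dist: Dist = field(
        default_factory=lambda: Dist("exponential", {"mean": 7.0})
    )
    active_intensity_dist: Dist = field(
        default_factory=lambda: Dist("lognormal", {"mu": 6.551, "sigma": 1.0})
    )
    sedentary_count_dist: Dist = field(
        default_factory=lambda: Dist("uniform_int", {"low": 1, "high": 199})
    )
    sleep_schedule: SleepSchedule = field(default_factory=SleepSchedule)
    nonwear_rate: float = 0.15  # expected episodes per day
    nonwear_duration_dist: Dist = field(
        default_factory=lambda: Dist("shifted_exponential", {"shift": 90.0, "mean": 45.0})
    )
    nonwear_min_minutes: int = 90
    outcome_model: dict = field(default_factory=default_outcome_model)
    seed: int = 0
    start_date: str = "2024-03-04"

    def validate(self) -> "SyntheticConfig":
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.n_days < 3:
            raise ConfigError("n_days must be >= 3 (first/last-day exclusion must leave >= 1 day)")
        if self.epoch_seconds != 60:
            raise ConfigError("epoch_seconds is fixed at 60")
        if self.nonwear_rate < 0:
            raise ConfigError("nonwear_rate must be >= 0")
        if self.nonwear_min_minutes < 1:
            raise ConfigError("nonwear_min_minutes must be >= 1")
        self.sleep_schedule.validate()
        sc = self.sedentary_count_dist
        if sc.family == "uniform_int" and not (0 <= sc.params["low"] and sc.params["high"] <= 199):
            raise ConfigError("sedentary_count_dist must be bounded within [0, 199]")
        return self

    def participant_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_participants)]


def _rng(config: SyntheticConfig, participant_id: str, stream: str) -> np.random.Generator:
    """Deterministic per-participant, per-stream generator from the one seed."""
    key = tuple(participant_id.encode()) + tuple(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key))


def _draw_schedule(config: SyntheticConfig, participant_id: str):
    """Per-day bed/wake minutes (after midnight), shared by series and diary."""
    sch = config.sleep_schedule
    rng = _rng(config, participant_id, "schedule")
    n = config.n_days
    bed = np.rint(rng.normal(sch.bed_mean_minute, sch.jitter_sd_minutes, n)).astype(int)
    wake = np.rint(rng.normal(sch.wake_mean_minute, sch.jitter_sd_minutes, n)).astype(int)
    bed = np.clip(bed, 1260, MINUTES_PER_DAY - 1)
    wake = np.clip(wake, 240, 720)
    return bed, wake


def _fill_alternating(rng, length, sed_dist, act_dist):
    """Label a waking window (0=sedentary, 1=active) by alternating renewal."""
    mean_cycle = sed_dist.mean() + act_dist.mean()
    p_sed_start = sed_dist.mean() / mean_cycle
    start_sed = rng.random() < p_sed_start
    labels = np.empty(length, dtype=np.int8)
    pos = 0
    state = 0 if start_sed else 1
    while pos < length:
        m = max(8, int(2 * (length - pos) / mean_cycle) + 2)
        sed = duration_minutes(sed_dist, rng, m)
        act = duration_minutes(act_dist, rng, m)
        durs = np.empty(2 * m, dtype=np.int64)
        if state == 0:
            durs[0::2], durs[1::2] = sed, act
        else:
            durs[0::2], durs[1::2] = act, sed
        for i, d in enumerate(durs):
            take = min(int(d), length - pos)
            labels[pos : pos + take] = (state + i) % 2
            pos += take
            if pos >= length:
                break
        state = (state + len(durs)) % 2  # resume alternation if we loop again
    return labels


# truth label codes
SLEEP, NONWEAR, SED, ACTIVE = 0, 1, 2, 3
TRUTH_NAMES = {SLEEP: "sleep", NONWEAR: "nonwear", SED: "sedentary", ACTIVE: "active"}

# Minimum waking-activity gap kept between injected nonwear and any adjacent
# zero-count region (sleep or other nonwear). Must exceed the nonwear
# detector's spike tolerance (default 2 min) so detection recovers the
# injected episodes exactly instead of bridging across short activity gaps.
NONWEAR_BUFFER_MINUTES = 3


def generate_epoch_series(config: SyntheticConfig, participant_id: str) -> EpochSeries:
    """Simulate one participant's full recording.

    Returns an :class:`EpochSeries` of ``n_days × 1440`` epochs whose
    ``meta['truth']`` holds the per-epoch truth labels, the true bout list
    (maximal sedentary runs, broken at midnight), and true per-day wear.
    """
    config.validate()
    rng = _rng(config, participant_id, "activity")
    n_days = config.n_days
    n = n_days * MINUTES_PER_DAY
    bed, wake = _draw_schedule(config, participant_id)

    truth = np.full(n, SLEEP, dtype=np.int8)
    # waking windows [wake_d, bed_d) within each day
    for d in range(n_days):
        w0 = d * MINUTES_PER_DAY + wake[d]
        w1 = d * MINUTES_PER_DAY + bed[d]
        seg = _fill_alternating(
            rng, w1 - w0, config.sedentary_bout_dist, config.active_bout_dist
        )
        truth[w0:w1] = np.where(seg == 0, SED, ACTIVE)

    # Nonwear episodes during waking time only; each spans >= the detector's
    # minimum run so injected nonwear is always recoverable. Episodes either
    # touch a waking-window edge or leave > NONWEAR_BUFFER_MINUTES of activity
    # on each side; otherwise a spike-tolerant detector could bridge the short
    # activity gap into the surrounding sleep zeros and flag waking minutes.
    for d in range(n_days):
        w0 = d * MINUTES_PER_DAY + wake[d]
        w1 = d * MINUTES_PER_DAY + bed[d]
        for _ in range(rng.poisson(config.nonwear_rate)):
            dur = int(duration_minutes(config.nonwear_duration_dist, rng, 1)[0])
            start = int(rng.integers(w0, w1))
            end = min(start + dur, w1)
            if end > w1 - NONWEAR_BUFFER_MINUTES:
                end = w1  # snap to bed time rather than leave a bridgeable gap
            if start < w0 + NONWEAR_BUFFER_MINUTES:
                start = w0
            if end - start < config.nonwear_min_minutes:
                continue
            # skip episodes that would sit within the buffer of existing nonwear
            pre = truth[max(w0, start - NONWEAR_BUFFER_MINUTES) : start]
            post = truth[end : min(w1, end + NONWEAR_BUFFER_MINUTES)]
            if (pre == NONWEAR).any() or (post == NONWEAR).any():
                continue
            truth[start:end] = NONWEAR

    counts = np.zeros(n, dtype=np.int64)
    sed_mask = truth == SED
    act_mask = truth == ACTIVE
    counts[sed_mask] = np.asarray(
        config.sedentary_count_dist.sample(rng, int(sed_mask.sum()))
    ).astype(np.int64)
    raw = np.asarray(config.active_intensity_dist.sample(rng, int(act_mask.sum())))
    counts[act_mask] = np.clip(np.rint(raw), 200, 50000).astype(np.int64)

    idx = pd.date_range(config.start_date, periods=n, freq="min")
    data = pd.DataFrame(
        {"axis1": counts, "axis2": 0, "axis3": 0}, index=idx, dtype=np.int64
    )
    data = _empty_flags(data)
    series = EpochSeries(participant_id=participant_id, data=data)
    compute_vector_magnitude(series)

    series.meta["truth"] = {
        "labels": truth,
        "bouts": _truth_bouts(truth, idx),
        "wear_minutes_per_day": _truth_wear_per_day(truth, n_days),
        "bed_minutes": bed.tolist(),
        "wake_minutes": wake.tolist(),
    }
    return series.validate()


def _truth_bouts(truth: np.ndarray, idx: pd.DatetimeIndex) -> pd.DataFrame:
    """Maximal sedentary runs in the truth labels, broken at midnight."""
    starts, durs = [], []
    n = len(truth)
    i = 0
    while i < n:
        if truth[i] == SED:
            j = i
            day = i // MINUTES_PER_DAY
            while j < n and truth[j] == SED and j // MINUTES_PER_DAY == day:
                j += 1
            starts.append(i)
            durs.append(j - i)
            i = j
        else:
            i += 1
    return pd.DataFrame(
        {"start_idx": starts, "start_time": idx[starts] if starts else idx[:0], "duration": durs}
    )


def _truth_wear_per_day(truth: np.ndarray, n_days: int) -> list[int]:
    per_day = truth.reshape(n_days, MINUTES_PER_DAY)
    return ((per_day == SED) | (per_day == ACTIVE)).sum(axis=1).astype(int).tolist()


def generate_sleep_diary(config: SyntheticConfig, participant_id: str) -> SleepDiary:
    """Diary records for the ``n_days − 1`` nights spanned by the recording.

    Night ``d`` runs from bed time on day ``d`` to wake time on day ``d+1``;
    the windows coincide exactly with the epochs zeroed as sleep by
    :func:`generate_epoch_series` for those nights.
    """
    config.validate()
    bed, wake = _draw_schedule(config, participant_id)
    start = pd.Timestamp(config.start_date)
    rows = []
    for d in range(config.n_days - 1):
        rows.append(
            {
                "bed_time": start + pd.Timedelta(days=d, minutes=int(bed[d])),
                "wake_time": start + pd.Timedelta(days=d + 1, minutes=int(wake[d + 1])),
            }
        )
    return SleepDiary(participant_id=participant_id, records=pd.DataFrame(rows)).validate()


def generate_covariates(config: SyntheticConfig, participant_id: str) -> dict:
    """Draw one participant's covariates (age, body fat %, binaries)."""
    rng = _rng(config, participant_id, "covariates")
    return {
        "participant_id": participant_id,
        "age": float(np.round(Dist("truncnormal", {"mean": 51.4, "sd": 7.6, "low": 30, "high": 75}).sample(rng), 1)),
        "body_fat_pct": float(np.round(Dist("truncnormal", {"mean": 40.1, "sd": 7.6, "low": 18, "high": 65}).sample(rng), 1)),
        "occupational_status": int(rng.random() < 0.263),
        "analgesic_use": int(rng.random() < 0.902),
        "antidepressant_use": int(rng.random() < 0.570),
    }


def generate_outcomes(config: SyntheticConfig, metrics: dict, covariates: dict) -> dict:
    """SF-36-like scores from the configured linear model plus Gaussian noise.

    Each score is ``intercept + Σ coef × predictor + N(0, noise_sd)``, clamped
    to [0, 100]. Predictors are looked up by name in ``metrics`` then
    ``covariates``; a missing predictor or outcome definition is an error.
    """
    pid = covariates["participant_id"]
    rng = _rng(config, pid, "outcomes")
    pool = {**covariates, **{k: v for k, v in metrics.items() if k != "participant_id"}}
    out = {"participant_id": pid}
    for name in SF36_ALL:
        if name not in config.outcome_model:
            raise ConfigError(f"outcome_model missing a definition for {name!r}")
        m = config.outcome_model[name]
        val = float(m["intercept"])
        for pred, coef in m["coef"].items():
            if pred not in pool:
                raise ConfigError(f"outcome {name!r}: unknown predictor {pred!r}")
            x = pool[pred]
            if x is None or (isinstance(x, float) and math.isnan(x)):
                x = 0.0  # participants with no qualifying bout contribute 0 exposure
            val += coef * float(x)
        val += rng.normal(0.0, m["noise_sd"]) if m["noise_sd"] > 0 else 0.0
        out[name] = float(min(100.0, max(0.0, val)))
    return out


# ---------------------------------------------------------------------------
# truth-side pattern summary (independent oracle for the measurement pipeline)
# ---------------------------------------------------------------------------

def truth_pattern_summary(
    series: EpochSeries,
    categories: tuple[int, ...] = (10, 20, 30, 60),
    min_valid_minutes: int = 600,
) -> dict:
    """Recompute the per-participant pattern metrics from truth labels alone.

    Mirrors the analysis conventions — first/last day dropped, a day valid
    when truth waking wear is at least ``min_valid_minutes`` — but reads only
    the generator's labels and bout list, never the detection code.
    """
    truth = series.meta["truth"]
    labels = truth["labels"]
    n_days = len(labels) // MINUTES_PER_DAY
    wear = truth["wear_minutes_per_day"]
    valid_days = [d for d in range(1, n_days - 1) if wear[d] >= min_valid_minutes]
    nvd = len(valid_days)
    out = {"participant_id": series.participant_id, "n_valid_days": nvd}
    if nvd == 0:
        return out
    vset = set(valid_days)
    per_day = labels.reshape(n_days, MINUTES_PER_DAY)
    wear_min = sum(int(((per_day[d] == SED) | (per_day[d] == ACTIVE)).sum()) for d in valid_days)
    st_min = sum(int((per_day[d] == SED).sum()) for d in valid_days)
    out["wear_minutes_per_day"] = wear_min / nvd
    out["st_minutes_per_day"] = st_min / nvd
    out["st_minutes_per_week"] = 7 * st_min / nvd
    bouts = truth["bouts"]
    on_valid = bouts[(bouts["start_idx"] // MINUTES_PER_DAY).isin(vset)]
    durs = on_valid["duration"].to_numpy()
    for L in categories:
        sel = durs[durs >= L]
        out[f"pct_st_in_bouts_{L}"] = 100.0 * sel.sum() / st_min if st_min else float("nan")
        out[f"bouts_per_sed_hour_{L}"] = len(sel) / (st_min / 60.0) if st_min else float("nan")
        out[f"bouts_per_week_{L}"] = 7.0 * len(sel) / nvd
    sel30 = durs[durs >= 30]
    out["mean_bout_duration_30"] = float(sel30.mean()) if len(sel30) else float("nan")
    return out


# ---------------------------------------------------------------------------
# whole-cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated cohort: epoch series, diaries, and the covariate/outcome table."""

    config: SyntheticConfig
    series: dict[str, EpochSeries]
    diaries: dict[str, SleepDiary]
    table: pd.DataFrame  # participant_id, covariates, outcomes
    truth_metrics: pd.DataFrame  # truth-side pattern summaries


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate the full cohort; outcomes depend on each participant's own
    (truth-side) pattern metrics, so effect-recovery tests have a known target."""
    config.validate()
    series, diaries, rows, truth_rows = {}, {}, [], []
    for pid in config.participant_ids():
        es = generate_epoch_series(config, pid)
        series[pid] = es
        diaries[pid] = generate_sleep_diary(config, pid)
        cov = generate_covariates(config, pid)
        metrics = truth_pattern_summary(es)
        truth_rows.append(metrics)
        rows.append({**cov, **generate_outcomes(config, metrics, cov)})
    cols = ["participant_id", *COVARIATE_COLUMNS, *SF36_ALL]
    return Cohort(
        config=config,
        series=series,
        diaries=diaries,
        table=pd.DataFrame(rows)[cols],
        truth_metrics=pd.DataFrame(truth_rows),
    )


def write_ground_truth(series: EpochSeries, path) -> None:
    """Write the truth sidecar (bout list, labels, schedule) as JSON."""
    truth = series.meta["truth"]
    payload = {
        "participant_id": series.participant_id,
        "labels": [TRUTH_NAMES[int(v)] for v in truth["labels"]],
        "bouts": [
            {"start_idx": int(r.start_idx), "duration": int(r.duration)}
            for r in truth["bouts"].itertuples()
        ],
        "wear_minutes_per_day": truth["wear_minutes_per_day"],
        "bed_minutes": truth["bed_minutes"],
        "wake_minutes": truth["wake_minutes"],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# cohort-level fast generator for simulation studies
# ---------------------------------------------------------------------------

def generate_analysis_table(
    config: SyntheticConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw an analysis table directly at participant level (no epoch data).

    Pattern metrics and covariates are drawn from marginal distributions
    matched to a realistic cohort; outcomes come from ``config.outcome_model``.
    This is the cheap route for replicated calibration studies (type-I error,
    CI coverage) where simulating epochs for every replicate adds nothing.
    """
    metrics = pd.DataFrame(
        {
            "pct_st_in_bouts_10": Dist("truncnormal", {"mean": 59.2, "sd": 11.2, "low": 0, "high": 100}).sample(rng, n),
            "pct_st_in_bouts_20": Dist("truncnormal", {"mean": 38.5, "sd": 12.8, "low": 0, "high": 100}).sample(rng, n),
            "pct_st_in_bouts_30": Dist("truncnormal", {"mean": 26.7, "sd": 12.3, "low": 0, "high": 100}).sample(rng, n),
            "pct_st_in_bouts_60": Dist("truncnormal", {"mean": 10.3, "sd": 8.9, "low": 0, "high": 100}).sample(rng, n),
            "st_minutes_per_week": Dist("truncnormal", {"mean": 3216.0, "sd": 700.0, "low": 500, "high": 7000}).sample(rng, n),
            "mean_bout_duration_30": Dist("truncnormal", {"mean": 47.7, "sd": 12.0, "low": 30, "high": 120}).sample(rng, n),
            "wear_minutes_per_day": Dist("truncnormal", {"mean": 923.0, "sd": 78.9, "low": 600, "high": 1200}).sample(rng, n),
            "mvpa_minutes_per_day": Dist("truncnormal", {"mean": 44.3, "sd": 30.1, "low": 0, "high": 200}).sample(rng, n),
        }
    )
    cov = pd.DataFrame(
        {
            "age": Dist("truncnormal", {"mean": 51.4, "sd": 7.6, "low": 30, "high": 75}).sample(rng, n),
            "body_fat_pct": Dist("truncnormal", {"mean": 40.1, "sd": 7.6, "low": 18, "high": 65}).sample(rng, n),
            "occupational_status": (rng.random(n) < 0.263).astype(int),
            "analgesic_use": (rng.random(n) < 0.902).astype(int),
            "antidepressant_use": (rng.random(n) < 0.570).astype(int),
        }
    )
    df = pd.concat([metrics, cov], axis=1)
    df.insert(0, "participant_id", [f"S{i:05d}" for i in range(n)])
    for name in SF36_ALL:
        m = config.outcome_model[name]
        val = np.full(n, float(m["intercept"]))
        for pred, coef in m["coef"].items():
            val = val + coef * df[pred].to_numpy(dtype=float)
        if m["noise_sd"] > 0:
            val = val + rng.normal(0.0, m["noise_sd"], n)
        df[name] = np.clip(val, 0.0, 100.0)
    return df


def with_outcome_model(config: SyntheticConfig, model: dict) -> SyntheticConfig:
    """Convenience: a copy of ``config`` with selected outcome definitions replaced."""
    merged = {**config.outcome_model, **model}
    return replace(config, outcome_model=merged)
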