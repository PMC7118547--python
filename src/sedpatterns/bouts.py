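"""Intensity classification, sedentary bout detection, and pattern summaries.

Intensity is classified on the per-epoch vector magnitude with the standard
triaxial cut points: sedentary below 200 cpm, moderate-to-vigorous at or
above 2690 cpm, light in between, with an additional configurable vigorous
threshold. A sedentary bout is a maximal run of consecutive sedentary wear
epochs within a valid analysis day; any non-sedentary epoch, nonwear or sleep
epoch, or day boundary ends the run — there is no interruption tolerance.

Two pattern statistics are computed per cumulative length category
L ∈ {10, 20, 30, 60} minutes:

* ``pct_st_in_bouts_L`` — 100 × (minutes in bouts ≥ L) / total sedentary time;
* ``bouts_per_sed_hour_L`` — (count of bouts ≥ L) / sedentary hours,

plus the descriptive weekly frequency ``bouts_per_week_L`` and the mean
duration of prolonged (≥ 30 min) bouts. Because categories are cumulative,
both occupancy and frequency are non-increasing in L, and bout durations sum
exactly to total sedentary time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EpochSeries

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES = (10, 20, 30, 60)

INTENSITY_LEVELS = ("sedentary", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class CutPoints:
    """Intensity thresholds in counts per minute on vector magnitude.

    ``sedentary_max`` is the highest whole cpm classified sedentary; on the
    floating-point vector magnitude the comparison is ``vm < sedentary_max + 1``.
    """

    sedentary_max: int = 199
    mvpa_min: int = 2690
    vigorous_min: int = 6167

    def validate(self) -> "CutPoints":
        if not (self.sedentary_max < self.mvpa_min <= self.vigorous_min):
            raise ValueError("require sedentary_max < mvpa_min <= vigorous_min")
        return self


@dataclass(frozen=True)
class SedentaryBout:
    """A maximal sedentary run: start timestamp and duration in minutes."""

    start: pd.Timestamp
    duration: int


def classify_intensity(series: EpochSeries, cuts: CutPoints = CutPoints()) -> EpochSeries:
    """Label wear epochs on valid days by intensity; all others stay NA."""
    cuts.validate()
    d = series.data
    vm = d["vm"].to_numpy(dtype=float)
    wear = (d["valid_day"] & ~d["sleep"] & ~d["nonwear"]).to_numpy()
    labels = np.full(len(d), None, dtype=object)
    labels[wear & (vm < cuts.sedentary_max + 1)] = "sedentary"
    labels[wear & (vm >= cuts.sedentary_max + 1) & (vm < cuts.mvpa_min)] = "light"
    labels[wear & (vm >= cuts.mvpa_min) & (vm < cuts.vigorous_min)] = "moderate"
    labels[wear & (vm >= cuts.vigorous_min)] = "vigorous"
    d["intensity"] = pd.array(labels, dtype="string")
    return series


def detect_sedentary_bouts(series: EpochSeries) -> list[SedentaryBout]:
    """Every maximal run of consecutive sedentary wear epochs within a valid day.

    Runs are broken by any non-sedentary label (including unclassified
    sleep/nonwear epochs) and by calendar-day boundaries.
    """
    d = series.data
    sed = (d["intensity"] == "sedentary").fillna(False).to_numpy(dtype=bool)
    if not sed.any():
        return []
    day_code = d.index.normalize().to_numpy()
    # a run continues while sedentary and on the same calendar day
    breaks = np.empty(len(sed), dtype=bool)
    breaks[0] = True
    breaks[1:] = (~sed[:-1]) | (day_code[1:] != day_code[:-1])
    run_id = np.cumsum(breaks & sed) * sed  # 0 where not sedentary
    bouts = []
    starts = np.nonzero(sed & breaks)[0]
    # durations via counts per run id
    ids, counts = np.unique(run_id[run_id > 0], return_counts=True)
    dur = dict(zip(ids.tolist(), counts.tolist()))
    for s in starts:
        bouts.append(SedentaryBout(start=d.index[s], duration=dur[int(run_id[s])]))
    return bouts


def summarize_patterns(
    series: EpochSeries,
    bouts: list[SedentaryBout],
    categories: tuple[int, ...] = DEFAULT_CATEGORIES,
) -> dict:
    """Per-participant volume and pattern metrics over the valid analysis days.

    Volumes are averaged per valid day and scaled ×7 for weekly figures.
    With zero sedentary time the ratio metrics are returned missing (NaN) and
    a warning is logged; the participant keeps their volume metrics.
    """
    d = series.data
    lab = d["intensity"]
    n_valid_days = len(set(d.index.normalize()[d["valid_day"].to_numpy()]))
    minutes = {lev: int((lab == lev).fillna(False).sum()) for lev in INTENSITY_LEVELS}
    wear_min = int(lab.notna().sum())
    st_min = minutes["sedentary"]
    mvpa_min = minutes["moderate"] + minutes["vigorous"]

    out: dict = {"participant_id": series.participant_id, "n_valid_days": n_valid_days}
    if n_valid_days == 0:
        logger.warning("%s: no valid days; pattern summary empty", series.participant_id)
        for key in _metric_columns(categories):
            out[key] = float("nan")
        return out

    out["wear_minutes_per_day"] = wear_min / n_valid_days
    out["st_minutes_per_day"] = st_min / n_valid_days
    out["st_minutes_per_week"] = 7.0 * st_min / n_valid_days
    out["light_minutes_per_day"] = minutes["light"] / n_valid_days
    out["moderate_minutes_per_day"] = minutes["moderate"] / n_valid_days
    out["vigorous_minutes_per_day"] = minutes["vigorous"] / n_valid_days
    out["mvpa_minutes_per_day"] = mvpa_min / n_valid_days

    durs = np.array([b.duration for b in bouts], dtype=np.int64)
    if st_min == 0:
        logger.warning(
            "%s: zero sedentary time; pattern ratios set to missing", series.participant_id
        )
    for L in categories:
        sel = durs[durs >= L] if durs.size else durs
        if st_min == 0:
            out[f"pct_st_in_bouts_{L}"] = float("nan")
            out[f"bouts_per_sed_hour_{L}"] = float("nan")
        else:
            out[f"pct_st_in_bouts_{L}"] = 100.0 * int(sel.sum()) / st_min
            out[f"bouts_per_sed_hour_{L}"] = len(sel) / (st_min / 60.0)
        out[f"bouts_per_week_{L}"] = 7.0 * len(sel) / n_valid_days
    sel30 = durs[durs >= 30] if durs.size else durs
    out["mean_bout_duration_30"] = float(sel30.mean()) if sel30.size else float("nan")
    return out


def _metric_columns(categories: tuple[int, ...]) -> list[str]:
    cols = [
        "wear_minutes_per_day",
        "st_minutes_per_day",
        "st_minutes_per_week",
        "light_minutes_per_day",
        "moderate_minutes_per_day",
        "vigorous_minutes_per_day",
        "mvpa_minutes_per_day",
    ]
    for L in categories:
        cols += [f"pct_st_in_bouts_{L}", f"bouts_per_sed_hour_{L}", f"bouts_per_week_{L}"]
    cols.append("mean_bout_duration_30")
    return cols


def pattern_table(
    summaries: list[dict], categories: tuple[int, ...] = DEFAULT_CATEGORIES
) -> pd.DataFrame:
    """Stack per-participant summaries into the analysis-ready table."""
    cols = ["participant_id", "n_valid_days", *_metric_columns(categories)]
    return pd.DataFrame(summaries).reindex(columns=cols)
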