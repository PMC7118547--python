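"""Wear validation: nonwear flagging, diary sleep exclusion, valid-day selection.

Nonwear follows the sustained-zero rule of Choi-type algorithms: a period of
at least ``nonwear_min_zeros`` minutes of zero counts, permitting up to
``spike_tolerance`` minutes of nonzero interruption provided each spike is
flanked by at least ``spike_flank_zeros`` minutes of zeros on both sides.
An epoch is flagged nonwear when *some* qualifying window contains it, so
flagged periods are maximal by construction.

Wear time is recorded time minus diary sleep and detected nonwear, counting
epochs carrying both flags once. Analysis days are calendar days; the first
and last recorded days are dropped, a remaining day is valid when waking wear
reaches the minimum, and a participant is retained when a long enough run of
consecutive valid days exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EpochSeries, SleepDiary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WearParams:
    """Parameters of nonwear detection and valid-day selection."""

    nonwear_min_zeros: int = 90  # minutes; minimum qualifying window
    spike_tolerance: int = 2  # allowed nonzero minutes inside a window
    spike_flank_zeros: int = 30  # zero minutes required on both sides of a spike
    min_valid_hours: float = 10.0
    required_days: int = 7  # consecutive valid days for retention
    drop_first_day: bool = True
    drop_last_day: bool = True

    def validate(self) -> "WearParams":
        if self.nonwear_min_zeros < 1 or self.min_valid_hours <= 0 or self.required_days < 1:
            raise ValueError("durations and day counts must be positive")
        if self.spike_tolerance < 0 or self.spike_flank_zeros < 0:
            raise ValueError("spike parameters must be >= 0")
        return self


def _runs(mask: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length encode a boolean array into (value, start, end) triples."""
    if len(mask) == 0:
        return []
    change = np.nonzero(np.diff(mask))[0] + 1
    bounds = np.concatenate(([0], change, [len(mask)]))
    return [
        (bool(mask[bounds[i]]), int(bounds[i]), int(bounds[i + 1]))
        for i in range(len(bounds) - 1)
    ]


def nonwear_mask(zero: np.ndarray, params: WearParams) -> np.ndarray:
    """Flag epochs covered by some qualifying sustained-zero window.

    A qualifying window starts and ends with zero epochs, spans at least
    ``nonwear_min_zeros`` minutes in total, contains at most
    ``spike_tolerance`` nonzero minutes, and every nonzero spike inside it is
    flanked by runs of at least ``spike_flank_zeros`` zeros on both sides.
    Spike minutes interior to a qualifying window are flagged too.
    """
    flags = np.zeros(len(zero), dtype=bool)
    runs = _runs(zero.astype(bool))
    for r, (is_zero, start, end) in enumerate(runs):
        if not is_zero:
            continue
        # extend rightwards over admissible spikes, tracking the longest
        # window that still qualifies; windows from this start are nested
        total = end - start
        spikes = 0
        best_end = end if total >= params.nonwear_min_zeros else None
        j = r
        while j + 2 < len(runs):
            s_len = runs[j + 1][2] - runs[j + 1][1]
            left_len = runs[j][2] - runs[j][1]
            right_len = runs[j + 2][2] - runs[j + 2][1]
            if spikes + s_len > params.spike_tolerance:
                break
            if left_len < params.spike_flank_zeros or right_len < params.spike_flank_zeros:
                break
            spikes += s_len
            total += s_len + right_len
            j += 2
            if total >= params.nonwear_min_zeros:
                best_end = runs[j][2]
        if best_end is not None:
            flags[start:best_end] = True
    return flags


def detect_nonwear(series: EpochSeries, params: WearParams, axis: str = "vm") -> EpochSeries:
    """Flag nonwear epochs on the chosen signal (vector magnitude by default).

    ``axis='axis1'`` reproduces vertical-axis-only detection for devices
    processed that way; zero vector magnitude and all-axes-zero coincide.
    """
    params.validate()
    sig = series.data[axis].to_numpy(dtype=float)
    if len(sig) < params.nonwear_min_zeros:
        series.data["nonwear"] = False
        return series
    series.data["nonwear"] = nonwear_mask(sig == 0, params)
    return series


def apply_sleep_exclusion(series: EpochSeries, diary: SleepDiary) -> EpochSeries:
    """Flag diary sleep windows ``[bed_time, wake_time)`` on the epoch grid.

    Interior calendar days without both a wake record (morning) and a bed
    record (evening) are noted in ``series.meta['diary_uncovered_days']``;
    they are later marked invalid rather than imputed.
    """
    diary.validate()
    idx = series.data.index
    sleep = np.zeros(len(idx), dtype=bool)
    for rec in diary.records.itertuples():
        lo = idx.searchsorted(rec.bed_time, side="left")
        hi = idx.searchsorted(rec.wake_time, side="left")
        sleep[lo:hi] = True
    series.data["sleep"] = sleep

    days = series.days()
    bed_days = {t.normalize() for t in diary.records["bed_time"]}
    wake_days = {t.normalize() for t in diary.records["wake_time"]}
    uncovered = [
        d for d in days[1:-1] if d not in bed_days or d not in wake_days
    ]
    if uncovered:
        logger.warning(
            "%s: no diary coverage for days %s; marked invalid",
            series.participant_id,
            [str(d.date()) for d in uncovered],
        )
    series.meta["diary_uncovered_days"] = uncovered
    return series


#: machine-readable exclusion reason codes (Figure-1-style flow accounting)
REASON_OK = "ok"
REASON_TOO_FEW_DAYS = "too_few_recorded_days"
REASON_NO_CONSECUTIVE_RUN = "insufficient_consecutive_valid_days"


@dataclass
class DaySelection:
    """Outcome of valid-day selection for one participant."""

    series: EpochSeries
    retained: bool
    reason_code: str
    day_table: pd.DataFrame = field(repr=False)  # date, wear_minutes, diary_covered, valid

    @property
    def n_valid_days(self) -> int:
        return int(self.day_table["valid"].sum())


def wear_minutes_by_day(series: EpochSeries) -> pd.Series:
    """Waking wear minutes per calendar day: epochs neither sleep nor nonwear."""
    d = series.data
    wear = ~(d["sleep"] | d["nonwear"])
    return wear.groupby(d.index.normalize()).sum()


def select_valid_days(series: EpochSeries, params: WearParams) -> DaySelection:
    """Drop first/last days, mark valid days, and decide participant retention.

    A day is valid when waking wear is at least ``min_valid_hours`` and the
    diary covers it; retention requires a run of at least ``required_days``
    consecutive valid calendar days. ``valid_day`` is set on every valid day.
    """
    params.validate()
    days = series.days()
    wear = wear_minutes_by_day(series)
    uncovered = set(series.meta.get("diary_uncovered_days", []))

    analysis_days = list(days)
    if params.drop_first_day and analysis_days:
        analysis_days = analysis_days[1:]
    if params.drop_last_day and analysis_days:
        analysis_days = analysis_days[:-1]

    rows = []
    min_minutes = params.min_valid_hours * 60
    for d in days:
        in_analysis = d in analysis_days
        w = int(wear.get(d, 0))
        valid = in_analysis and d not in uncovered and w >= min_minutes
        rows.append(
            {
                "date": d,
                "wear_minutes": w,
                "analysis_day": in_analysis,
                "diary_covered": d not in uncovered,
                "valid": valid,
            }
        )
    table = pd.DataFrame(rows)

    valid_days = set(table.loc[table["valid"], "date"])
    norm = series.data.index.normalize()
    series.data["valid_day"] = norm.isin(valid_days)

    if not analysis_days:
        return DaySelection(series, False, REASON_TOO_FEW_DAYS, table)
    retained = _max_consecutive_valid(sorted(valid_days)) >= params.required_days
    reason = REASON_OK if retained else REASON_NO_CONSECUTIVE_RUN
    return DaySelection(series, retained, reason, table)


def _max_consecutive_valid(valid_dates: list) -> int:
    """Longest run of calendar-consecutive dates."""
    best = run = 0
    prev = None
    for d in valid_dates:
        run = run + 1 if prev is not None and (d - prev).days == 1 else 1
        best = max(best, run)
        prev = d
    return best


def exclusion_report(selections: dict[str, DaySelection]) -> pd.DataFrame:
    """One row per participant: retention decision and reason code."""
    rows = []
    for pid in sorted(selections):
        sel = selections[pid]
        rows.append(
            {
                "participant_id": pid,
                "retained": sel.retained,
                "reason_code": sel.reason_code,
                "n_valid_days": sel.n_valid_days,
                "detail": f"valid_days={sel.n_valid_days}",
            }
        )
    return pd.DataFrame(rows, columns=["participant_id", "retained", "reason_code", "n_valid_days", "detail"])
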