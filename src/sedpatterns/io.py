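"""File formats for the pipeline: epoch counts, sleep diaries, covariates/outcomes.

All three formats are plain UTF-8 comma-separated files with a mandatory header
row, documented column by column below. Readers validate and reject; they never
repair. Write-then-read is the identity for every type.

Epoch CSV
    ``participant_id,timestamp,axis1,axis2,axis3`` — one row per minute,
    ISO-8601 timezone-naive timestamps at strict 60-s spacing, non-negative
    integer counts per axis.

Sleep diary CSV
    ``participant_id,bed_time,wake_time`` — one row per night, ISO-8601
    datetimes, ``wake_time > bed_time``, non-overlapping records.

Covariates/outcomes CSV
    ``participant_id,age,body_fat_pct,occupational_status,analgesic_use,
    antidepressant_use`` followed by the eight SF-36 domain columns and the
    two component summaries (all scored 0–100). Binary covariates are coded
    1 = working / medication yes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

#: The eight SF-36 health domains, each scored 0 (worst) to 100 (best).
SF36_DOMAINS = (
    "physical_function",
    "physical_role",
    "bodily_pain",
    "general_health",
    "vitality",
    "social_functioning",
    "emotional_role",
    "mental_health",
)
#: Physical and mental component summaries.
SF36_SUMMARIES = ("pcs", "mcs")
SF36_ALL = SF36_DOMAINS + SF36_SUMMARIES

COVARIATE_COLUMNS = (
    "age",
    "body_fat_pct",
    "occupational_status",
    "analgesic_use",
    "antidepressant_use",
)

EPOCH_COLUMNS = ("participant_id", "timestamp", "axis1", "axis2", "axis3")
DIARY_COLUMNS = ("participant_id", "bed_time", "wake_time")

EPOCH_SECONDS = 60


@dataclass
class EpochSeries:
    """One participant's minute-epoch triaxial count stream plus annotations.

    ``data`` is indexed by a strictly consecutive minute-resolution
    DatetimeIndex and carries the three axis counts, the derived vector
    magnitude, boolean ``sleep`` / ``nonwear`` / ``valid_day`` flags and an
    ``intensity`` label column (filled downstream; NA until classified).
    ``meta`` holds bookkeeping such as diary-uncovered days.
    """

    participant_id: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def vm(self) -> np.ndarray:
        return self.data["vm"].to_numpy()

    def validate(self) -> "EpochSeries":
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise IntegrityError(f"{self.participant_id}: index must be datetimes")
        if len(idx) > 1:
            deltas = np.diff(idx.asi8) / 1e9
            bad = np.nonzero(deltas != EPOCH_SECONDS)[0]
            if bad.size:
                i = int(bad[0])
                raise IntegrityError(
                    f"{self.participant_id}: epochs not at strict 60-s spacing; "
                    f"first bad row {i + 1} ({idx[i]} -> {idx[i + 1]})"
                )
        for c in ("axis1", "axis2", "axis3"):
            col = self.data[c].to_numpy()
            if np.any(col < 0):
                row = int(np.nonzero(col < 0)[0][0])
                raise IntegrityError(
                    f"{self.participant_id}: negative count in column {c}, row {row}"
                )
        return self

    def days(self) -> list:
        """Sorted unique calendar days covered by the series."""
        return sorted(set(self.data.index.normalize()))


@dataclass
class SleepDiary:
    """Per-night bed/wake records for one participant.

    ``records`` has columns ``bed_time`` and ``wake_time``; windows are
    half-open ``[bed_time, wake_time)`` and must not overlap.
    """

    participant_id: str
    records: pd.DataFrame

    def validate(self) -> "SleepDiary":
        rec = self.records.sort_values("bed_time").reset_index(drop=True)
        bad = rec["wake_time"] <= rec["bed_time"]
        if bad.any():
            i = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValidationError(
                f"{self.participant_id}: diary row {i}: wake_time "
                f"{rec['wake_time'][i]} not after bed_time {rec['bed_time'][i]}"
            )
        if len(rec) > 1:
            overlap = rec["bed_time"].iloc[1:].to_numpy() < rec["wake_time"].iloc[:-1].to_numpy()
            if overlap.any():
                i = int(np.nonzero(overlap)[0][0])
                raise ValidationError(
                    f"{self.participant_id}: diary rows {i} and {i + 1} overlap"
                )
        self.records = rec
        return self


def compute_vector_magnitude(series: EpochSeries) -> EpochSeries:
    """Populate ``vm`` as the per-epoch Euclidean norm of the three axis counts."""
    d = series.data
    x = d["axis1"].to_numpy(dtype=float)
    y = d["axis2"].to_numpy(dtype=float)
    z = d["axis3"].to_numpy(dtype=float)
    d["vm"] = np.sqrt(x * x + y * y + z * z)
    return series


def _empty_flags(df: pd.DataFrame) -> pd.DataFrame:
    for c in ("sleep", "nonwear", "valid_day"):
        if c not in df.columns:
            df[c] = False
    if "intensity" not in df.columns:
        df["intensity"] = pd.array([pd.NA] * len(df), dtype="string")
    return df


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_epoch_csv(path) -> EpochSeries:
    """Read one participant's epoch CSV into a validated :class:`EpochSeries`."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, EPOCH_COLUMNS, path)
    pids = df["participant_id"].astype(str).unique()
    if len(pids) != 1:
        raise FormatError(f"{path}: expected exactly one participant_id, found {list(pids)}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparsable timestamp ({exc})") from exc
    counts = df[["axis1", "axis2", "axis3"]]
    if counts.isna().any().any():
        raise IntegrityError(f"{path}: missing axis counts")
    out = counts.astype(np.int64)
    out.index = pd.DatetimeIndex(ts.to_numpy())
    out = _empty_flags(out)
    series = EpochSeries(participant_id=str(pids[0]), data=out)
    compute_vector_magnitude(series)
    return series.validate()


def write_epoch_csv(series: EpochSeries, path) -> None:
    d = series.data
    out = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "timestamp": d.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "axis1": d["axis1"].to_numpy(),
            "axis2": d["axis2"].to_numpy(),
            "axis3": d["axis3"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)


def read_sleep_diary(path) -> dict[str, SleepDiary]:
    """Read the diary CSV; returns a mapping participant_id -> SleepDiary."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, DIARY_COLUMNS, path)
    try:
        df["bed_time"] = pd.to_datetime(df["bed_time"], format="ISO8601")
        df["wake_time"] = pd.to_datetime(df["wake_time"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparsable diary datetime ({exc})") from exc
    diaries = {}
    for pid, grp in df.groupby(df["participant_id"].astype(str), sort=True):
        diaries[pid] = SleepDiary(
            participant_id=pid,
            records=grp[["bed_time", "wake_time"]].reset_index(drop=True),
        ).validate()
    return diaries


def write_sleep_diaries(diaries: dict[str, SleepDiary], path) -> None:
    rows = []
    for pid in sorted(diaries):
        rec = diaries[pid].records
        for _, r in rec.iterrows():
            rows.append(
                {
                    "participant_id": pid,
                    "bed_time": r["bed_time"].strftime("%Y-%m-%dT%H:%M:%S"),
                    "wake_time": r["wake_time"].strftime("%Y-%m-%dT%H:%M:%S"),
                }
            )
    pd.DataFrame(rows, columns=DIARY_COLUMNS).to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    """Read and validate the covariate/outcome table, keyed by participant_id.

    Returns a DataFrame with ``participant_id`` as a string column, covariates,
    and all ten SF-36 scores, each validated to lie in [0, 100].
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ("participant_id",) + COVARIATE_COLUMNS + SF36_ALL
    _require_columns(df, required, path)
    df["participant_id"] = df["participant_id"].astype(str)
    dup = df["participant_id"].duplicated()
    if dup.any():
        pid = df["participant_id"][dup].iloc[0]
        raise ValidationError(f"{path}: duplicate participant_id {pid!r}")
    ages = df["age"].to_numpy(dtype=float)
    if np.any(ages <= 0):
        raise ValidationError(f"{path}: non-positive age for participant "
                              f"{df['participant_id'][ages <= 0].iloc[0]!r}")
    fat = df["body_fat_pct"].to_numpy(dtype=float)
    if np.any((fat < 0) | (fat > 100)):
        raise ValidationError(f"{path}: body_fat_pct out of [0,100]")
    for c in ("occupational_status", "analgesic_use", "antidepressant_use"):
        vals = set(df[c].dropna().unique())
        if not vals <= {0, 1}:
            raise ValidationError(f"{path}: column {c} must be coded 0/1, got {sorted(vals)}")
    for c in SF36_ALL:
        v = df[c].to_numpy(dtype=float)
        bad = (v < 0) | (v > 100)
        if bad.any():
            pid = df["participant_id"][bad].iloc[0]
            raise ValidationError(
                f"{path}: {c}={v[bad][0]} out of [0,100] for participant {pid!r}"
            )
    return df.reset_index(drop=True)


def write_covariates(df: pd.DataFrame, path) -> None:
    cols = ["participant_id", *COVARIATE_COLUMNS, *SF36_ALL]
    df[cols].to_csv(path, index=False)


def check_linkage(covariates: pd.DataFrame, ids) -> None:
    """Verify every epoch-file participant appears in the covariate table."""
    from .errors import LinkageError

    known = set(covariates["participant_id"])
    unknown = sorted(set(map(str, ids)) - known)
    if unknown:
        raise LinkageError(f"participants with no covariate record: {unknown}")
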