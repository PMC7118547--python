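"""Nonwear detection, sleep exclusion, and valid-day selection contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_series
from oracles import nonwear_reference, zero_run_reference
from sedpatterns import (
    SleepDiary,
    SyntheticConfig,
    WearParams,
    apply_sleep_exclusion,
    detect_nonwear,
    generate_epoch_series,
    generate_sleep_diary,
    select_valid_days,
)
from sedpatterns.wear import (
    REASON_NO_CONSECUTIVE_RUN,
    REASON_OK,
    nonwear_mask,
    wear_minutes_by_day,
)

P = WearParams()


def _active(n, value=300):
    return [value] * n


class TestNonwearExamples:
    def test_120_zero_minutes_all_flagged(self):
        s = make_series(_active(30) + [0] * 120 + _active(30))
        detect_nonwear(s, P)
        nw = s.data["nonwear"].to_numpy()
        assert nw[30:150].all()
        assert not nw[:30].any() and not nw[150:].any()

    def test_89_zero_minutes_none_flagged(self):
        s = make_series(_active(30) + [0] * 89 + _active(30))
        detect_nonwear(s, P)
        assert not s.data["nonwear"].any()

    def test_exactly_90_zero_minutes_flagged(self):
        s = make_series(_active(10) + [0] * 90 + _active(10))
        detect_nonwear(s, P)
        assert s.data["nonwear"].to_numpy()[10:100].all()

    def test_spike_with_30min_flanks_keeps_window(self):
        # 40 zeros, one 50-cpm spike, 55 zeros: window of 96 min qualifies
        s = make_series(_active(30) + [0] * 40 + [50] + [0] * 55 + _active(30))
        detect_nonwear(s, P)
        nw = s.data["nonwear"].to_numpy()
        assert nw[30 : 30 + 96].all()
        assert not nw[:30].any() and not nw[126:].any()

    def test_spike_10min_from_edge_breaks_window(self):
        s = make_series(_active(30) + [0] * 10 + [50] + [0] * 85 + _active(30))
        detect_nonwear(s, P)
        assert not s.data["nonwear"].any()

    def test_spike_budget_exceeded_splits_adjacent_windows(self):
        # two qualifying zero runs separated by a 3-min spike (> tolerance 2)
        s = make_series(_active(5) + [0] * 100 + [50] * 3 + [0] * 95 + _active(5))
        detect_nonwear(s, P)
        nw = s.data["nonwear"].to_numpy()
        assert nw[5:105].all()
        assert not nw[105:108].any()
        assert nw[108:203].all()

    def test_short_series_returns_unchanged(self):
        s = make_series([0] * 50)
        detect_nonwear(s, P)
        assert not s.data["nonwear"].any()

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        counts = np.where(rng.random(2000) < 0.4, 0, rng.integers(1, 400, 2000))
        s = make_series(counts)
        detect_nonwear(s, P)
        once = s.data["nonwear"].copy()
        detect_nonwear(s, P)
        pd.testing.assert_series_equal(once, s.data["nonwear"])


def _random_zero_pattern(rng, n_days):
    """Structured random series: zero/nonzero blocks with boundary-rich lengths."""
    n = n_days * 1440
    out = np.empty(n, dtype=np.int64)
    pos = 0
    while pos < n:
        if rng.random() < 0.5:
            length = int(rng.choice([1, 2, 3, 29, 30, 31, 60, 88, 89, 90, 91, 120, 200]))
            val = 0
        else:
            length = int(rng.choice([1, 2, 3, 4, 10, 30, 60, 120]))
            val = int(rng.integers(1, 500))
        out[pos : pos + min(length, n - pos)] = val
        pos += length
    return out


class TestNonwearOracle:
    def test_matches_literal_window_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            zero = _random_zero_pattern(rng, int(rng.integers(1, 3))) == 0
            got = nonwear_mask(zero, P)
            want = nonwear_reference(zero, P.nonwear_min_zeros, P.spike_tolerance, P.spike_flank_zeros)
            np.testing.assert_array_equal(got, want)

    def test_zero_tolerance_degenerates_to_run_length_scan(self):
        rng = np.random.default_rng(1)
        params = WearParams(spike_tolerance=0)
        for _ in range(200):
            zero = rng.random(int(rng.integers(100, 2000))) < 0.55
            got = nonwear_mask(zero, params)
            want = zero_run_reference(zero, params.nonwear_min_zeros)
            np.testing.assert_array_equal(got, want)

    @given(st.integers(0, 2**31 - 1))
    def test_flagged_epochs_only_within_zero_or_spike_context(self, seed):
        """Flags never extend past the enclosing run structure."""
        rng = np.random.default_rng(seed)
        zero = _random_zero_pattern(rng, 1) == 0
        got = nonwear_mask(zero, P)
        want = nonwear_reference(zero, 90, 2, 30)
        np.testing.assert_array_equal(got, want)


def _diary(pid, windows):
    return SleepDiary(
        participant_id=pid,
        records=pd.DataFrame(
            [{"bed_time": pd.Timestamp(b), "wake_time": pd.Timestamp(w)} for b, w in windows]
        ),
    )


class TestSleepExclusion:
    def test_midnight_crossing_window_flags_480_epochs(self):
        s = make_series(_active(2 * 1440), start="2024-03-04")
        d = _diary("T0", [("2024-03-04 23:00", "2024-03-05 07:00")])
        apply_sleep_exclusion(s, d)
        sleep = s.data["sleep"]
        assert int(sleep.sum()) == 480
        # split across the midnight boundary: 60 min on day 1, 420 on day 2
        by_day = sleep.groupby(s.data.index.normalize()).sum()
        assert list(by_day) == [60, 420]

    def test_sleep_nonwear_overlap_counted_once_in_wear(self):
        counts = _active(600) + [0] * 240 + _active(1440 * 2 - 840)
        s = make_series(counts, start="2024-03-04")
        detect_nonwear(s, P)
        # sleep window overlapping the first 120 min of the nonwear run
        d = _diary("T0", [("2024-03-04 08:00", "2024-03-04 12:00")])
        apply_sleep_exclusion(s, d)
        dd = s.data
        both = dd["sleep"] & dd["nonwear"]
        assert both.any()
        day1 = dd[dd.index.normalize() == pd.Timestamp("2024-03-04")]
        excluded = (day1["sleep"] | day1["nonwear"]).sum()
        wear = wear_minutes_by_day(s)[pd.Timestamp("2024-03-04")]
        assert wear == 1440 - excluded

    def test_uncovered_interior_day_recorded(self):
        s = make_series(_active(4 * 1440), start="2024-03-04")
        d = _diary(
            "T0",
            [
                ("2024-03-04 23:00", "2024-03-05 07:00"),
                # no record for the night starting 2024-03-05
                ("2024-03-06 23:00", "2024-03-07 07:00"),
            ],
        )
        apply_sleep_exclusion(s, d)
        uncovered = {str(x.date()) for x in s.meta["diary_uncovered_days"]}
        assert uncovered == {"2024-03-05", "2024-03-06"}

    def test_wear_matches_generator_ground_truth(self):
        cfg = SyntheticConfig(n_days=7, seed=55)
        s = generate_epoch_series(cfg, "P0000")
        detect_nonwear(s, P)
        apply_sleep_exclusion(s, generate_sleep_diary(cfg, "P0000"))
        wear = wear_minutes_by_day(s)
        truth = s.meta["truth"]["wear_minutes_per_day"]
        # interior days: diary covers the whole sleep; first/last are dropped
        for d in range(1, cfg.n_days - 1):
            assert wear.iloc[d] == truth[d]


def _flagged_series(wear_by_day):
    """Series with sleep flags arranged so each day has the given wear minutes."""
    n_days = len(wear_by_day)
    s = make_series(_active(n_days * 1440), start="2024-03-04")
    sleep = np.ones(n_days * 1440, dtype=bool)
    for d, w in enumerate(wear_by_day):
        sleep[d * 1440 : d * 1440 + w] = False
    s.data["sleep"] = sleep
    s.meta["diary_uncovered_days"] = []
    return s


class TestValidDays:
    def test_nine_good_days_retains_with_seven_valid(self):
        sel = select_valid_days(_flagged_series([14 * 60] * 9), P)
        assert sel.retained and sel.reason_code == REASON_OK
        assert sel.n_valid_days == 7
        t = sel.day_table
        assert not t["valid"].iloc[0] and not t["valid"].iloc[-1]

    def test_exactly_10h_wear_is_valid(self):
        sel = select_valid_days(_flagged_series([600] * 9), P)
        assert sel.retained and sel.n_valid_days == 7

    def test_9p9_hours_breaks_the_run(self):
        days = [14 * 60] * 9
        days[4] = 594  # 9.9 h in the middle of the only candidate window
        sel = select_valid_days(_flagged_series(days), P)
        assert not sel.retained
        assert sel.reason_code == REASON_NO_CONSECUTIVE_RUN

    def test_exactly_seven_valid_days_retained(self):
        sel = select_valid_days(_flagged_series([0] + [600] * 7 + [0] * 2 + [0]), P)
        assert sel.retained

    def test_uncovered_day_invalid(self):
        s = _flagged_series([14 * 60] * 9)
        s.meta["diary_uncovered_days"] = [pd.Timestamp("2024-03-08")]
        sel = select_valid_days(s, P)
        assert not sel.retained

    def test_retention_matches_exhaustive_window_search(self):
        rng = np.random.default_rng(77)
        for _ in range(150):
            n_days = int(rng.integers(3, 12))
            wear = rng.choice([0, 300, 599, 600, 601, 900], size=n_days)
            sel = select_valid_days(_flagged_series(list(wear)), P)
            valid = [w >= 600 for w in wear[1:-1]]
            # brute force: any window of 7 consecutive valid interior days
            expect = any(
                all(valid[i : i + 7]) for i in range(max(0, len(valid) - 6))
            ) and len(valid) >= 7
            assert sel.retained == expect
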