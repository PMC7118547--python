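import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sedpatterns import (
    CutPoints,
    SyntheticConfig,
    WearParams,
    apply_sleep_exclusion,
    classify_intensity,
    detect_nonwear,
    detect_sedentary_bouts,
    generate_epoch_series,
    generate_sleep_diary,
    select_valid_days,
    summarize_patterns,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def process_participant(config: SyntheticConfig, pid: str, wear=None, cuts=None,
                        categories=(10, 20, 30, 60)):
    """Run one generated participant through the full measurement pipeline."""
    wear = wear or WearParams()
    cuts = cuts or CutPoints()
    series = generate_epoch_series(config, pid)
    detect_nonwear(series, wear)
    apply_sleep_exclusion(series, generate_sleep_diary(config, pid))
    sel = select_valid_days(series, wear)
    bouts, summary = [], None
    if sel.retained:
        classify_intensity(series, cuts)
        bouts = detect_sedentary_bouts(series)
        summary = summarize_patterns(series, bouts, categories)
    return series, sel, bouts, summary


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_participants=5, seed=123)


@pytest.fixture(scope="session")
def processed_cohort():
    """40 generated participants run through the measurement pipeline."""
    config = SyntheticConfig(n_participants=40, seed=2024)
    out = []
    for pid in config.participant_ids():
        out.append(process_participant(config, pid))
    return config, out


def make_series(counts, start="2024-03-04", participant_id="T0"):
    """Build an EpochSeries directly from a vm-like count vector (axis1 only)."""
    from sedpatterns.io import EpochSeries, _empty_flags, compute_vector_magnitude

    counts = np.asarray(counts, dtype=np.int64)
    idx = pd.date_range(start, periods=len(counts), freq="min")
    data = pd.DataFrame({"axis1": counts, "axis2": 0, "axis3": 0}, index=idx)
    data = _empty_flags(data)
    series = EpochSeries(participant_id=participant_id, data=data)
    compute_vector_magnitude(series)
    return series
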