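import datetime as dt

import numpy as np
import pandas as pd
import pytest

from actidiary.diary_met import CompendiumTable, MetSlotSeries
from actidiary.signal_enmo import EnmoSlotSeries, RawDaySpan
from actidiary.windows import DayWindow

DATE = dt.date(2020, 3, 2)


@pytest.fixture
def window() -> DayWindow:
    return DayWindow()


@pytest.fixture
def small_table() -> CompendiumTable:
    return CompendiumTable(
        pd.DataFrame(
            {
                "activity": ["walking", "watching tv", "housekeeping", "resting"],
                "intensity": ["moderate", "mild", "moderate", "any"],
                "code": ["17170", "07020", "05035", "07030"],
                "met": [3.5, 1.3, 3.3, 1.0],
            }
        )
    )


def make_enmo_day(
    pid: str = "P1",
    date: dt.date = DATE,
    position: str = "ankle",
    values: np.ndarray | float = 0.05,
    valid: np.ndarray | bool = True,
    window: DayWindow = DayWindow(),
) -> EnmoSlotSeries:
    n = window.n_slots
    vals = np.full(n, values, dtype=float) if np.isscalar(values) else np.asarray(values, float)
    v = np.full(n, valid, dtype=bool) if np.isscalar(valid) else np.asarray(valid, bool)
    cov = np.where(v, 1.0, 0.0)
    return EnmoSlotSeries(
        participant_id=pid,
        date=date,
        sensor_position=position,
        window=window,
        enmo_mean=vals,
        coverage=cov,
        valid=v,
    )


def make_met_day(
    pid: str = "P1",
    date: dt.date = DATE,
    values: np.ndarray | float = 3.0,
    valid: np.ndarray | bool = True,
    non_wear: np.ndarray | bool = False,
    n_entries: int = 5,
    window: DayWindow = DayWindow(),
) -> MetSlotSeries:
    n = window.n_slots
    vals = np.full(n, values, dtype=float) if np.isscalar(values) else np.asarray(values, float)
    v = np.full(n, valid, dtype=bool) if np.isscalar(valid) else np.asarray(valid, bool)
    nw = np.full(n, non_wear, dtype=bool) if np.isscalar(non_wear) else np.asarray(non_wear, bool)
    return MetSlotSeries(
        participant_id=pid,
        date=date,
        window=window,
        met_low=vals,
        met_avg=vals,
        met_high=vals,
        n_activities=v.astype(int),
        valid=v,
        non_wear=nw,
        n_entries=n_entries,
    )


def full_span(window: DayWindow = DayWindow()) -> RawDaySpan:
    return RawDaySpan(start_s=window.start_s, end_s=window.end_s, covered_s=window.end_s - window.start_s)
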