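import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from actidiary.diary_met import (
    CompendiumTable,
    DiaryEntry,
    assign_met,
    diary_to_slots,
    load_bundled_compendium,
    parse_diary,
)
from actidiary.errors import DataError
from actidiary.windows import DayWindow

DATE = dt.date(2020, 1, 2)


def row(start, end, activity, intensity="moderate", non_wear=0, pid="P01", date="2020-01-02"):
    return {
        "participant": pid,
        "date": date,
        "start": start,
        "end": end,
        "activity": activity,
        "intensity": intensity,
        "non_wear": non_wear,
        "comment": "",
    }


def entry(start_h, end_h, label, intensity="moderate", non_wear=False, pid="P01"):
    return DiaryEntry(
        participant_id=pid,
        date=DATE,
        start_s=start_h * 3600.0,
        end_s=end_h * 3600.0,
        activity_label=label,
        intensity=intensity,
        non_wear=non_wear,
    )


class TestParseDiary:
    def test_single_valid_row(self):
        entries, rejects = parse_diary(pd.DataFrame([row("09:00", "09:30", "walking")]))
        assert len(entries) == 1 and len(rejects) == 0
        assert entries[0].duration_s == pytest.approx(1800.0)

    def test_negative_duration_rejected(self):
        entries, rejects = parse_diary(pd.DataFrame([row("09:00", "08:00", "walking")]))
        assert len(entries) == 0
        assert rejects.iloc[0]["reason"] == "negative duration"

    def test_unknown_intensity_rejected(self):
        _, rejects = parse_diary(pd.DataFrame([row("09:00", "10:00", "walking", "extreme")]))
        assert "unknown intensity" in rejects.iloc[0]["reason"]

    def test_parallel_entries_coexist(self):
        entries, _ = parse_diary(
            pd.DataFrame(
                [row("10:00", "10:30", "housekeeping"), row("10:00", "10:30", "watching tv", "mild")]
            )
        )
        assert len(entries) == 2

    def test_missing_column_errors(self):
        with pytest.raises(DataError, match="missing required columns"):
            parse_diary(pd.DataFrame([{"participant": "P01"}]))

    def test_sub_threshold_flagged(self):
        entries, _ = parse_diary(pd.DataFrame([row("09:00", "09:10", "walking")]))
        assert entries[0].sub_threshold

    def test_non_wear_row_without_activity(self):
        entries, rejects = parse_diary(pd.DataFrame([row("09:00", "10:00", "", "", non_wear=1)]))
        assert len(rejects) == 0
        assert entries[0].non_wear


class TestAssignMet:
    def test_direct_lookup(self, small_table):
        assert assign_met(entry(9, 10, "walking"), small_table) == pytest.approx(3.5)

    def test_mild_tv(self, small_table):
        assert assign_met(entry(9, 10, "watching TV", "mild"), small_table) == pytest.approx(1.3)

    def test_unmapped_activity(self, small_table):
        assert assign_met(entry(9, 10, "zorbing", "vigorous"), small_table) is None

    def test_label_fallback_any(self, small_table):
        assert assign_met(entry(9, 10, "resting", "vigorous"), small_table) == pytest.approx(1.0)

    def test_bundled_table_loads(self):
        table = load_bundled_compendium()
        assert len(table) > 40
        assert table.lookup("walking", "moderate")[1] > 0

    def test_duplicate_key_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            CompendiumTable(
                pd.DataFrame(
                    {
                        "activity": ["walking", "walking"],
                        "intensity": ["mild", "mild"],
                        "code": ["1", "2"],
                        "met": [2.0, 3.0],
                    }
                )
            )


class TestDiaryToSlots:
    def test_single_activity_two_slots(self, small_table, window):
        out = diary_to_slots([entry(9.0, 9.5, "walking")], small_table, window)
        for i in (0, 1):
            assert out.met_low[i] == out.met_avg[i] == out.met_high[i] == pytest.approx(3.5)
            assert out.valid[i]
        assert not out.valid[2]

    def test_parallel_activities_min_mean_max(self, small_table, window):
        entries = [entry(10.0, 10.25, "housekeeping"), entry(10.0, 10.25, "watching tv", "mild")]
        out = diary_to_slots(entries, small_table, window)
        slot = window.slot_of(10.0 * 3600)
        assert out.met_low[slot] == pytest.approx(1.3)
        assert out.met_avg[slot] == pytest.approx(2.3)
        assert out.met_high[slot] == pytest.approx(3.3)
        assert out.n_activities[slot] == 2

    def test_non_wear_only_slot_invalid(self, small_table, window):
        out = diary_to_slots([entry(9.0, 9.25, "", None, non_wear=True)], small_table, window)
        assert not out.valid[0]
        assert out.non_wear[0]
        assert np.isnan(out.met_low[0])

    def test_unmapped_excluded_and_counted(self, small_table, window):
        out = diary_to_slots([entry(9.0, 9.5, "zorbing")], small_table, window)
        assert out.n_unmapped == 1
        assert not out.valid.any()

    def test_half_overlap_rule(self, small_table, window):
        # 09:00-09:05 overlaps slot 0 by 5 min < 50% -> excluded under "half"
        short = entry(9.0, 9 + 5 / 60, "walking")
        assert not diary_to_slots([short], small_table, window, "half").valid[0]
        assert diary_to_slots([short], small_table, window, "any").valid[0]

    def test_mixed_day_rejected(self, small_table):
        e1 = entry(9, 10, "walking")
        e2 = entry(9, 10, "walking", pid="P02")
        with pytest.raises(DataError, match="single participant-day"):
            diary_to_slots([e1, e2], small_table)

    def test_permutation_invariance(self, small_table, window):
        entries = [
            entry(9.0, 11.0, "walking"),
            entry(10.0, 12.5, "housekeeping"),
            entry(11.5, 13.0, "watching tv", "mild"),
        ]
        a = diary_to_slots(entries, small_table, window)
        b = diary_to_slots(entries[::-1], small_table, window)
        np.testing.assert_array_equal(a.met_low, b.met_low)
        np.testing.assert_array_equal(a.met_avg, b.met_avg)
        np.testing.assert_array_equal(a.met_high, b.met_high)

    def test_valid_slot_count_bounded(self, small_table, window):
        out = diary_to_slots([entry(7.0, 20.0, "walking")], small_table, window)
        assert out.valid.sum() <= 36


@st.composite
def random_day(draw):
    n = draw(st.integers(1, 8))
    entries, mets = [], {}
    for i in range(n):
        start = draw(st.integers(9 * 4, 18 * 4 - 1))  # quarter-hours
        length = draw(st.integers(1, 12))
        label = f"act{i}"
        mets[label] = draw(st.floats(0.9, 12.0, allow_nan=False))
        entries.append(
            DiaryEntry(
                participant_id="P01",
                date=DATE,
                start_s=start * 900.0,
                end_s=min((start + length) * 900.0, 24 * 3600.0 - 1),
                activity_label=label,
                intensity="moderate",
            )
        )
    return entries, mets


@settings(max_examples=200, deadline=None)
@given(random_day())
def test_level_ordering_property(day):
    entries, mets = day
    table = CompendiumTable(
        pd.DataFrame(
            {
                "activity": list(mets),
                "intensity": ["any"] * len(mets),
                "code": ["x"] * len(mets),
                "met": list(mets.values()),
            }
        )
    )
    out = diary_to_slots(entries, table, DayWindow())
    mask = out.valid
    assert np.all(out.met_low[mask] <= out.met_avg[mask] + 1e-12)
    assert np.all(out.met_avg[mask] <= out.met_high[mask] + 1e-12)
    assert mask.sum() <= 36
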