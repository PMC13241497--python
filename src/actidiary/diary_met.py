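"""Activity diaries -> Compendium MET values -> 15-minute slot series.

Each diary entry records an activity label, start/end times and a
self-reported intensity (mild / moderate / vigorous).  The (label,
intensity) pair is looked up in a Compendium-style table to obtain a MET
value.  Because entries may overlap in time (parallel activities), each
slot carries three MET levels: low (minimum of the concurrent activities),
average (duration-weighted mean) and high (maximum).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .windows import DayWindow, DEFAULT_WINDOW, parse_time_of_day

log = logging.getLogger(__name__)

INTENSITIES = ("mild", "moderate", "vigorous")
FALLBACK_INTENSITY = "any"
MIN_ENTRY_SECONDS = 15 * 60.0

__all__ = [
    "DiaryEntry",
    "CompendiumTable",
    "MetSlotSeries",
    "parse_diary",
    "assign_met",
    "diary_to_slots",
    "load_bundled_compendium",
    "met_series_frame",
]


@dataclass
class DiaryEntry:
    participant_id: str
    date: dt.date
    start_s: float
    end_s: float
    activity_label: str
    intensity: str | None
    non_wear: bool = False
    comment: str = ""
    sub_threshold: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise DataError("diary entry must have positive duration")
        self.sub_threshold = (self.end_s - self.start_s) < MIN_ENTRY_SECONDS

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_with(self, start_s: float, end_s: float) -> float:
        return max(0.0, min(self.end_s, end_s) - max(self.start_s, start_s))


def _norm_label(label: str) -> str:
    return " ".join(str(label).strip().lower().split())


class CompendiumTable:
    """Lookup of (activity label, intensity) -> (compendium code, MET).

    Rows with intensity ``any`` act as label-only fallbacks for entries
    whose exact (label, intensity) pair is not in the table.
    """

    def __init__(self, rows: pd.DataFrame):
        required = {"activity", "intensity", "code", "met"}
        if not required.issubset(rows.columns):
            raise DataError(f"compendium table missing columns {sorted(required - set(rows.columns))}")
        self._map: dict[tuple[str, str], tuple[str, float]] = {}
        for _, r in rows.iterrows():
            met = float(r["met"])
            if met <= 0:
                raise DataError(f"non-positive MET for activity {r['activity']!r}")
            key = (_norm_label(r["activity"]), str(r["intensity"]).strip().lower())
            if key in self._map:
                raise DataError(f"duplicate compendium key {key}")
            self._map[key] = (str(r["code"]), met)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompendiumTable":
        return cls(pd.read_csv(path))

    def lookup(self, label: str, intensity: str | None) -> tuple[str, float] | None:
        """Exact (label, intensity) match, falling back to a label-only
        ``any`` row; None when unmapped."""
        norm = _norm_label(label)
        if intensity is not None:
            hit = self._map.get((norm, str(intensity).strip().lower()))
            if hit is not None:
                return hit
        return self._map.get((norm, FALLBACK_INTENSITY))

    def __len__(self) -> int:
        return len(self._map)


def load_bundled_compendium() -> CompendiumTable:
    """Editable table of common activities x intensities shipped with the
    package (not claimed authoritative)."""
    with resources.files("actidiary.data").joinpath("compendium.csv").open() as fh:
        return CompendiumTable(pd.read_csv(fh))


@dataclass
class MetSlotSeries:
    """Low/average/high MET per 15-minute slot for one participant-day.

    ``valid`` means at least one mapped, non-non-wear activity covers the
    slot; ``non_wear`` flags slots covered by an explicit non-wear entry
    (these invalidate both arms downstream).
    """

    participant_id: str
    date: dt.date
    window: DayWindow
    met_low: np.ndarray
    met_avg: np.ndarray
    met_high: np.ndarray
    n_activities: np.ndarray
    valid: np.ndarray
    non_wear: np.ndarray
    n_entries: int = 0
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        n = self.window.n_slots
        for name in ("met_low", "met_avg", "met_high", "n_activities", "valid", "non_wear"):
            if getattr(self, name).shape != (n,):
                raise DataError(f"{name} must have exactly {n} slots")


_TRUTHY = {"1", "true", "yes", "y", "t"}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return str(value).strip().lower() in _TRUTHY


def parse_diary(rows: pd.DataFrame) -> tuple[list[DiaryEntry], pd.DataFrame]:
    """Validate tabular diary records into entries.

    Overlapping entries are permitted (parallel activities).  Malformed rows
    are not silently dropped: they are returned as a report frame with a
    ``reason`` column.
    """
    required = {"participant", "date", "start", "end", "activity", "intensity"}
    missing = required - set(rows.columns)
    if missing:
        raise DataError(f"diary is missing required columns {sorted(missing)}")

    entries: list[DiaryEntry] = []
    rejects: list[dict] = []
    for idx, r in rows.iterrows():
        reason = None
        try:
            start = parse_time_of_day(r["start"])
            end = parse_time_of_day(r["end"])
        except (ValueError, TypeError):
            reason = "unparseable start/end time"
            start = end = None
        non_wear = _parse_bool(r.get("non_wear"))
        intensity = r.get("intensity")
        intensity = None if pd.isna(intensity) or str(intensity).strip() == "" else str(intensity).strip().lower()
        if reason is None and end <= start:
            reason = "negative duration" if end < start else "zero duration"
        if reason is None and intensity is not None and intensity not in INTENSITIES:
            reason = f"unknown intensity token {intensity!r}"
        if reason is None and intensity is None and not non_wear:
            reason = "missing intensity"
        label = "" if pd.isna(r.get("activity")) else str(r["activity"]).strip()
        if reason is None and not label and not non_wear:
            reason = "missing activity label"
        if reason is not None:
            rejects.append({**{k: r.get(k) for k in rows.columns}, "row": idx, "reason": reason})
            continue
        entries.append(
            DiaryEntry(
                participant_id=str(r["participant"]),
                date=dt.date.fromisoformat(str(r["date"])),
                start_s=start,
                end_s=end,
                activity_label=label or ("non-wear" if non_wear else ""),
                intensity=intensity,
                non_wear=non_wear,
                comment="" if pd.isna(r.get("comment")) else str(r.get("comment")),
            )
        )
    report = pd.DataFrame(rejects)
    if len(report):
        log.info("rejected %d malformed diary rows", len(report))
    return entries, report


def assign_met(entry: DiaryEntry, table: CompendiumTable) -> float | None:
    """MET value for one entry; None flags the entry unmapped (excluded
    from the series and surfaced in the QC report)."""
    if entry.non_wear:
        return None
    hit = table.lookup(entry.activity_label, entry.intensity)
    return None if hit is None else hit[1]


def diary_to_slots(
    entries: list[DiaryEntry],
    table: CompendiumTable,
    window: DayWindow = DEFAULT_WINDOW,
    overlap_rule: str = "half",
) -> MetSlotSeries:
    """Map one participant-day's entries onto the 15-minute slot grid.

    overlap_rule:
      * ``"half"`` -- an entry contributes to a slot it overlaps by at least
        50% of the slot duration (default; avoids boundary double counting).
      * ``"any"`` -- any positive overlap contributes.

    Per slot, over the contributing non-non-wear activities: ``met_low`` is
    the minimum MET, ``met_high`` the maximum, ``met_avg`` the
    duration-weighted mean (weights = overlap seconds within the slot).
    """
    if overlap_rule not in ("half", "any"):
        raise DataError(f"unknown overlap rule: {overlap_rule!r}")
    if entries:
        pids = {e.participant_id for e in entries}
        dates = {e.date for e in entries}
        if len(pids) > 1 or len(dates) > 1:
            raise DataError("diary_to_slots expects entries from a single participant-day")

    n = window.n_slots
    met_low = np.full(n, np.nan)
    met_avg = np.full(n, np.nan)
    met_high = np.full(n, np.nan)
    n_act = np.zeros(n, dtype=int)
    non_wear = np.zeros(n, dtype=bool)
    threshold = 0.5 * window.slot_s if overlap_rule == "half" else 0.0

    mets: list[float] = []
    mapped: list[DiaryEntry] = []
    n_unmapped = 0
    for e in entries:
        if e.non_wear:
            mapped.append(e)
            mets.append(np.nan)
            continue
        met = assign_met(e, table)
        if met is None:
            n_unmapped += 1
            log.info("unmapped activity %r (%s)", e.activity_label, e.intensity)
            continue
        mapped.append(e)
        mets.append(met)

    starts = window.slot_starts
    for i, s0 in enumerate(starts):
        s1 = s0 + window.slot_s
        vals: list[float] = []
        weights: list[float] = []
        for e, met in zip(mapped, mets):
            ov = e.overlap_with(s0, s1)
            contributes = ov >= threshold if threshold > 0 else ov > 0
            if not contributes:
                continue
            if e.non_wear:
                non_wear[i] = True
                continue
            vals.append(met)
            weights.append(ov)
        if vals:
            v = np.asarray(vals)
            w = np.asarray(weights)
            met_low[i] = v.min()
            met_high[i] = v.max()
            met_avg[i] = float(np.sum(v * w) / np.sum(w))
            n_act[i] = len(vals)

    valid = n_act >= 1
    return MetSlotSeries(
        participant_id=entries[0].participant_id if entries else "",
        date=entries[0].date if entries else dt.date(1970, 1, 1),
        window=window,
        met_low=met_low,
        met_avg=met_avg,
        met_high=met_high,
        n_activities=n_act,
        valid=valid,
        non_wear=non_wear,
        n_entries=len(entries),
        n_unmapped=n_unmapped,
    )


def met_series_frame(series: MetSlotSeries) -> pd.DataFrame:
    """Tidy frame: ``participant,date,slot_start,met_low,met_avg,met_high,
    n_activities,valid``."""
    return pd.DataFrame(
        {
            "participant": series.participant_id,
            "date": series.date.isoformat(),
            "slot_start": series.window.slot_labels(),
            "met_low": series.met_low,
            "met_avg": series.met_avg,
            "met_high": series.met_high,
            "n_activities": series.n_activities,
            "valid": series.valid,
            "non_wear": series.non_wear,
        }
    )
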