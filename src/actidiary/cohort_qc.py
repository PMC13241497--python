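"""Day- and participant-level inclusion rules; aligned ENMO/MET panels.

A participant-day enters the analysis only when (i) the sensor recording
spans the whole daytime window, (ii) enough sensor time was recorded,
(iii) the diary has at least one entry, and (iv) at least four 15-minute
slots are valid in BOTH arms simultaneously.  Participants need at least
three included days per sensor to be retained.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diary_met import MetSlotSeries
from .errors import DataError, EmptyCohortError
from .signal_enmo import EnmoSlotSeries, RawDaySpan

log = logging.getLogger(__name__)

__all__ = [
    "InclusionRules",
    "DayRecord",
    "CohortDay",
    "CohortPanel",
    "validate_day",
    "build_cohort",
    "qc_report_frame",
    "cohort_summary",
]


@dataclass(frozen=True)
class InclusionRules:
    """Thresholds controlling day/participant inclusion.

    ``sensor_hours_mode``: ``"covered"`` (default, stricter: sum of recorded
    time) or ``"span"`` (wall-clock extent of the recording).
    """

    min_simultaneous_slots: int = 4
    min_days: int = 3
    min_sensor_hours: float = 9.0
    require_window_span: bool = True
    sensor_hours_mode: str = "covered"

    def __post_init__(self) -> None:
        if self.sensor_hours_mode not in ("covered", "span"):
            raise DataError(f"unknown sensor_hours_mode: {self.sensor_hours_mode!r}")
        if self.min_simultaneous_slots < 0 or self.min_days < 1:
            raise DataError("inclusion thresholds out of range")


@dataclass
class DayRecord:
    """QC outcome for one participant-day-sensor."""

    participant_id: str
    date: dt.date
    sensor_position: str
    enmo: EnmoSlotSeries
    met: MetSlotSeries
    joint_valid: np.ndarray
    simultaneity: int
    sensor_hours_ok: bool
    window_ok: bool
    diary_present: bool
    simultaneity_ok: bool
    included: bool
    reasons: list[str] = field(default_factory=list)


def validate_day(
    enmo_day: EnmoSlotSeries,
    met_day: MetSlotSeries,
    raw_span: RawDaySpan,
    rules: InclusionRules = InclusionRules(),
) -> DayRecord:
    """Apply the day-level inclusion rules to one aligned participant-day.

    The joint-validity mask requires the slot to be valid in both arms and
    not flagged non-wear by the diary.
    """
    if enmo_day.participant_id != met_day.participant_id or enmo_day.date != met_day.date:
        raise DataError(
            f"arm mismatch: ENMO is {enmo_day.participant_id}/{enmo_day.date}, "
            f"diary is {met_day.participant_id}/{met_day.date}"
        )
    if enmo_day.window.n_slots != met_day.window.n_slots:
        raise DataError("ENMO and MET slot grids differ")

    window = enmo_day.window
    joint = enmo_day.valid & met_day.valid & ~met_day.non_wear
    simultaneity = int(joint.sum())

    if rules.sensor_hours_mode == "covered":
        sensor_seconds = raw_span.covered_s
    else:
        sensor_seconds = (
            raw_span.end_s - raw_span.start_s if np.isfinite(raw_span.start_s) else 0.0
        )
    sensor_hours_ok = sensor_seconds >= rules.min_sensor_hours * 3600.0

    window_ok = True
    if rules.require_window_span:
        window_ok = (
            np.isfinite(raw_span.start_s)
            and raw_span.start_s <= window.start_s
            and raw_span.end_s >= window.end_s
        )

    diary_present = met_day.n_entries >= 1
    simultaneity_ok = simultaneity >= rules.min_simultaneous_slots
    included = sensor_hours_ok and window_ok and diary_present and simultaneity_ok

    reasons = []
    if not sensor_hours_ok:
        reasons.append("sensor_hours")
    if not window_ok:
        reasons.append("window")
    if not diary_present:
        reasons.append("diary_missing")
    if not simultaneity_ok:
        reasons.append("simultaneity")

    return DayRecord(
        participant_id=enmo_day.participant_id,
        date=enmo_day.date,
        sensor_position=enmo_day.sensor_position,
        enmo=enmo_day,
        met=met_day,
        joint_valid=joint,
        simultaneity=simultaneity,
        sensor_hours_ok=sensor_hours_ok,
        window_ok=window_ok,
        diary_present=diary_present,
        simultaneity_ok=simultaneity_ok,
        included=included,
        reasons=reasons,
    )


@dataclass
class CohortDay:
    """One included day's aligned slot vectors for one sensor and MET level."""

    date: dt.date
    enmo: np.ndarray  # (n_slots,), NaN where invalid
    met: np.ndarray
    mask: np.ndarray  # joint validity

    @property
    def n_epochs(self) -> int:
        return int(self.mask.sum())


@dataclass
class CohortPanel:
    """Post-QC participant x day x slot panel, one sensor x MET level."""

    sensor_position: str
    met_level: str
    participants: dict[str, list[CohortDay]]
    n_slots: int

    def epoch_count(self, participant_id: str) -> int:
        return sum(d.n_epochs for d in self.participants[participant_id])

    @property
    def total_epochs(self) -> int:
        return sum(self.epoch_count(p) for p in self.participants)

    @property
    def total_days(self) -> int:
        return sum(len(v) for v in self.participants.values())

    def enmo_values(self) -> np.ndarray:
        """All joint-valid ENMO values across participants/days/slots."""
        vals = [d.enmo[d.mask] for days in self.participants.values() for d in days]
        return np.concatenate(vals) if vals else np.empty(0)

    def met_values(self) -> np.ndarray:
        vals = [d.met[d.mask] for days in self.participants.values() for d in days]
        return np.concatenate(vals) if vals else np.empty(0)

    def transformed(self, enmo_fn, met_fn) -> "CohortPanel":
        """New panel with both arms mapped through the given callables."""
        out: dict[str, list[CohortDay]] = {}
        for pid, days in self.participants.items():
            out[pid] = [
                CohortDay(date=d.date, enmo=enmo_fn(d.enmo), met=met_fn(d.met), mask=d.mask.copy())
                for d in days
            ]
        return CohortPanel(
            sensor_position=self.sensor_position,
            met_level=self.met_level,
            participants=out,
            n_slots=self.n_slots,
        )


_MET_ARRAYS = {"low": "met_low", "avg": "met_avg", "high": "met_high"}


def build_cohort(
    day_records: list[DayRecord],
    sensor_position: str,
    met_level: str,
    min_days: int = 3,
) -> CohortPanel:
    """Assemble the post-QC panel for one sensor x MET level.

    Participants with fewer than ``min_days`` included days are dropped;
    raises :class:`EmptyCohortError` when nobody survives.
    """
    if met_level not in _MET_ARRAYS:
        raise DataError(f"unknown MET level: {met_level!r}")
    per_participant: dict[str, list[CohortDay]] = {}
    n_slots = None
    for rec in day_records:
        if rec.sensor_position != sensor_position or not rec.included:
            continue
        n_slots = rec.enmo.window.n_slots
        met_arr = getattr(rec.met, _MET_ARRAYS[met_level]).copy()
        enmo_arr = rec.enmo.enmo_mean.copy()
        enmo_arr[~rec.joint_valid] = np.nan
        met_arr[~rec.joint_valid] = np.nan
        per_participant.setdefault(rec.participant_id, []).append(
            CohortDay(date=rec.date, enmo=enmo_arr, met=met_arr, mask=rec.joint_valid.copy())
        )

    retained = {p: days for p, days in per_participant.items() if len(days) >= min_days}
    dropped = sorted(set(per_participant) - set(retained))
    if dropped:
        log.info("dropped %d participants with < %d included days: %s", len(dropped), min_days, dropped)
    if not retained:
        raise EmptyCohortError(
            f"no participants left for sensor={sensor_position}, level={met_level} "
            f"after requiring >= {min_days} included days"
        )
    return CohortPanel(
        sensor_position=sensor_position,
        met_level=met_level,
        participants=dict(sorted(retained.items())),
        n_slots=n_slots or 36,
    )


def qc_report_frame(day_records: list[DayRecord]) -> pd.DataFrame:
    """Per participant-day-sensor flags and exclusion reasons."""
    return pd.DataFrame(
        {
            "participant": [r.participant_id for r in day_records],
            "date": [r.date.isoformat() for r in day_records],
            "position": [r.sensor_position for r in day_records],
            "simultaneity": [r.simultaneity for r in day_records],
            "sensor_hours_ok": [r.sensor_hours_ok for r in day_records],
            "window_ok": [r.window_ok for r in day_records],
            "diary_present": [r.diary_present for r in day_records],
            "simultaneity_ok": [r.simultaneity_ok for r in day_records],
            "included": [r.included for r in day_records],
            "reasons": [";".join(r.reasons) for r in day_records],
        }
    )


def cohort_summary(panels: dict[tuple[str, str], CohortPanel], day_records: list[DayRecord]) -> dict:
    """Machine-readable cohort summary (participants, days, epochs,
    exclusion tallies)."""
    report = qc_report_frame(day_records)
    tallies: dict[str, int] = {}
    for reasons in report.loc[~report["included"], "reasons"]:
        for reason in filter(None, reasons.split(";")):
            tallies[reason] = tallies.get(reason, 0) + 1
    return {
        "n_day_records": len(day_records),
        "n_days_included": int(report["included"].sum()),
        "n_days_excluded": int((~report["included"]).sum()),
        "exclusion_tallies": tallies,
        "panels": {
            f"{sensor}/{level}": {
                "participants": len(panel.participants),
                "days": panel.total_days,
                "epochs": panel.total_epochs,
            }
            for (sensor, level), panel in panels.items()
        },
    }
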