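"""Day-window and slot-grid helpers.

Everything downstream works on a fixed daytime analysis window divided into
15-minute slots.  Times inside a day are represented as seconds since
midnight (float), which keeps slot arithmetic exact and avoids timezone
handling entirely.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

SECONDS_PER_MINUTE = 60.0
SECONDS_PER_HOUR = 3600.0

__all__ = ["DayWindow", "parse_time_of_day", "seconds_to_hhmm", "DEFAULT_WINDOW"]


def parse_time_of_day(value: str | float | int | dt.time) -> float:
    """Convert ``HH:MM[:SS]`` strings, :class:`datetime.time` or plain
    numbers into seconds since midnight."""
    if isinstance(value, (int, float)):
        sec = float(value)
    elif isinstance(value, dt.time):
        sec = value.hour * 3600.0 + value.minute * 60.0 + value.second + value.microsecond / 1e6
    else:
        parts = str(value).strip().split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"cannot parse time of day: {value!r}")
        h, m = int(parts[0]), int(parts[1])
        s = float(parts[2]) if len(parts) == 3 else 0.0
        sec = h * 3600.0 + m * 60.0 + s
    if not 0.0 <= sec <= 24 * 3600.0:
        raise ValueError(f"time of day out of range: {value!r}")
    return sec


def seconds_to_hhmm(sec: float) -> str:
    sec = int(round(sec))
    return f"{sec // 3600:02d}:{(sec % 3600) // 60:02d}"


@dataclass(frozen=True)
class DayWindow:
    """Half-open daytime analysis window ``[start_s, end_s)`` on a slot grid.

    The default 09:00-18:00 window yields 36 fifteen-minute slots, the last
    one being 17:45-18:00.
    """

    start_s: float = 9 * SECONDS_PER_HOUR
    end_s: float = 18 * SECONDS_PER_HOUR
    slot_s: float = 15 * SECONDS_PER_MINUTE

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("window end must be after window start")
        if self.slot_s <= 0:
            raise ValueError("slot duration must be positive")
        span = self.end_s - self.start_s
        if abs(span / self.slot_s - round(span / self.slot_s)) > 1e-9:
            raise ValueError(
                f"window span {span:.0f} s is not a whole multiple of the "
                f"{self.slot_s:.0f} s slot duration"
            )

    @property
    def n_slots(self) -> int:
        return int(round((self.end_s - self.start_s) / self.slot_s))

    @property
    def slot_starts(self) -> np.ndarray:
        return self.start_s + self.slot_s * np.arange(self.n_slots)

    def slot_of(self, t: float) -> int:
        """Slot index containing time-of-day ``t``; -1 if outside window."""
        if t < self.start_s or t >= self.end_s:
            return -1
        return int((t - self.start_s) // self.slot_s)

    def slot_labels(self) -> list[str]:
        return [seconds_to_hhmm(s) for s in self.slot_starts]

    @classmethod
    def from_strings(cls, start: str, end: str, slot_minutes: float = 15.0) -> "DayWindow":
        return cls(
            start_s=parse_time_of_day(start),
            end_s=parse_time_of_day(end),
            slot_s=slot_minutes * SECONDS_PER_MINUTE,
        )


DEFAULT_WINDOW = DayWindow()
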