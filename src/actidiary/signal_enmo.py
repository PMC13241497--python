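"""Raw tri-axial acceleration -> ENMO on 5-second epochs -> 15-minute slots.

ENMO (Euclidean Norm Minus One) is the magnitude of the acceleration vector
minus 1 g, low-pass filtered and truncated at zero so that only the dynamic
component of movement remains.  The per-sample series is averaged over
non-overlapping 5-second epochs anchored to the wall clock, and those epoch
means are averaged again over the 15-minute slots of the daytime window.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DataError, NyquistError
from .windows import DayWindow, DEFAULT_WINDOW

log = logging.getLogger(__name__)

EPOCH_SECONDS = 5.0

__all__ = [
    "FilterConfig",
    "RawAccelRecording",
    "EnmoSampleSeries",
    "EnmoEpochSeries5s",
    "EnmoSlotSeries",
    "RawDaySpan",
    "compute_enmo",
    "aggregate_5s",
    "aggregate_slots",
    "read_raw_recording",
    "read_epoch_csv",
    "write_epoch_csv",
    "slot_series_frame",
]

SENSOR_POSITIONS = ("ankle", "wrist", "lower_back")


@dataclass(frozen=True)
class FilterConfig:
    """Low-pass filter settings for ENMO extraction.

    placement:
      * ``"post_norm"`` -- filter the (norm - 1 g) signal, then truncate
        negatives (default; literal processing order).
      * ``"per_axis"`` -- filter each axis before the norm (common field
        alternative).
      * ``"none"`` -- identity filter; norm - 1 g is truncated directly.
    """

    order: int = 4
    cutoff_hz: float = 20.0
    placement: str = "post_norm"

    def __post_init__(self) -> None:
        if self.placement not in ("post_norm", "per_axis", "none"):
            raise ValueError(f"unknown filter placement: {self.placement!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff frequency must be positive")


@dataclass
class RawAccelRecording:
    """One sensor's tri-axial samples for a single participant-day.

    ``timestamps`` are seconds since midnight of ``date``; accelerations are
    in gravitational units [g].
    """

    participant_id: str
    sensor_position: str
    date: dt.date
    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.sensor_position not in SENSOR_POSITIONS:
            raise DataError(f"unknown sensor position: {self.sensor_position!r}")
        n = self.timestamps.size
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise DataError("axis arrays must match timestamp length")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise DataError("timestamps must be strictly increasing")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size


@dataclass
class EnmoSampleSeries:
    """Per-sample ENMO [g], aligned to the retained input timestamps."""

    timestamps: np.ndarray
    enmo: np.ndarray
    n_dropped_nonfinite: int = 0

    def __post_init__(self) -> None:
        if self.timestamps.size != self.enmo.size:
            raise DataError("enmo and timestamps must have equal length")


@dataclass
class EnmoEpochSeries5s:
    """Mean ENMO on the wall-clock 5-second grid; epochs with no samples
    are simply absent."""

    epoch_start: np.ndarray  # seconds since midnight, multiples of 5
    enmo_mean: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self) -> None:
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.enmo_mean = np.asarray(self.enmo_mean, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.epoch_start.size


@dataclass
class EnmoSlotSeries:
    """ENMO aggregated to the 15-minute slot grid of one day.

    Always carries exactly ``window.n_slots`` entries; slots without any
    5-second epoch have ``enmo_mean`` NaN and coverage 0.
    """

    participant_id: str
    date: dt.date
    sensor_position: str
    window: DayWindow
    enmo_mean: np.ndarray
    coverage: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        n = self.window.n_slots
        for name in ("enmo_mean", "coverage", "valid"):
            if getattr(self, name).shape != (n,):
                raise DataError(f"{name} must have exactly {n} slots")


@dataclass(frozen=True)
class RawDaySpan:
    """Wall-clock extent and covered duration of one day's sensor data."""

    start_s: float
    end_s: float
    covered_s: float

    @classmethod
    def from_epochs(cls, epochs: EnmoEpochSeries5s) -> "RawDaySpan":
        if epochs.n_epochs == 0:
            return cls(start_s=float("nan"), end_s=float("nan"), covered_s=0.0)
        return cls(
            start_s=float(epochs.epoch_start.min()),
            end_s=float(epochs.epoch_start.max()) + EPOCH_SECONDS,
            covered_s=float(epochs.n_epochs * EPOCH_SECONDS),
        )


def compute_enmo(raw: RawAccelRecording, filter_cfg: FilterConfig | None = None) -> EnmoSampleSeries:
    """Per-sample ENMO: ``norm(ax, ay, az) - 1 g``, low-pass filtered
    (zero-phase Butterworth), negatives truncated to zero.

    Raises :class:`NyquistError` when the sampling rate does not exceed
    twice the cutoff, and :class:`DataError` on an empty recording.
    """
    cfg = filter_cfg or FilterConfig()
    if raw.n_samples == 0:
        raise DataError("cannot compute ENMO of an empty recording")

    finite = np.isfinite(raw.ax) & np.isfinite(raw.ay) & np.isfinite(raw.az)
    n_dropped = int((~finite).sum())
    if n_dropped:
        frac = n_dropped / raw.n_samples
        log.info("dropped %d non-finite samples (%.2f%%)", n_dropped, 100 * frac)
        if frac > 0.05:
            warnings.warn(
                f"{100 * frac:.1f}% non-finite samples in "
                f"{raw.participant_id} {raw.date} {raw.sensor_position}",
                stacklevel=2,
            )
    t = raw.timestamps[finite]
    ax, ay, az = raw.ax[finite], raw.ay[finite], raw.az[finite]
    if t.size == 0:
        raise DataError("recording contains no finite samples")

    if cfg.placement == "none":
        enmo = np.sqrt(ax * ax + ay * ay + az * az) - 1.0
    else:
        if raw.sampling_rate <= 2.0 * cfg.cutoff_hz:
            raise NyquistError(
                f"sampling rate {raw.sampling_rate} Hz violates the Nyquist "
                f"requirement for a {cfg.cutoff_hz} Hz cutoff (need > {2 * cfg.cutoff_hz} Hz)"
            )
        sos = sps.butter(cfg.order, cfg.cutoff_hz, btype="low", fs=raw.sampling_rate, output="sos")
        if cfg.placement == "per_axis":
            ax, ay, az = (_sosfiltfilt(sos, a) for a in (ax, ay, az))
            enmo = np.sqrt(ax * ax + ay * ay + az * az) - 1.0
        else:  # post_norm
            enmo = np.sqrt(ax * ax + ay * ay + az * az) - 1.0
            enmo = _sosfiltfilt(sos, enmo)

    np.maximum(enmo, 0.0, out=enmo)
    return EnmoSampleSeries(timestamps=t, enmo=enmo, n_dropped_nonfinite=n_dropped)


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # filtfilt needs a few filter lengths of signal; fall back to the raw
    # signal only for pathologically short inputs.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= padlen:
        raise DataError(
            f"recording too short to filter ({x.size} samples; need > {padlen})"
        )
    return sps.sosfiltfilt(sos, x)


def aggregate_5s(enmo: EnmoSampleSeries, sampling_rate: float | None = None) -> EnmoEpochSeries5s:
    """Arithmetic mean of per-sample ENMO over non-overlapping 5-second
    epochs anchored on the wall clock; epochs without samples are absent."""
    if enmo.timestamps.size == 0:
        return EnmoEpochSeries5s(
            epoch_start=np.empty(0), enmo_mean=np.empty(0), n_samples=np.empty(0, dtype=int)
        )
    idx = np.floor(enmo.timestamps / EPOCH_SECONDS).astype(np.int64)
    uniq, inverse, counts = np.unique(idx, return_inverse=True, return_counts=True)
    sums = np.bincount(inverse, weights=enmo.enmo, minlength=uniq.size)
    return EnmoEpochSeries5s(
        epoch_start=uniq * EPOCH_SECONDS,
        enmo_mean=sums / counts,
        n_samples=counts,
    )


def aggregate_slots(
    epochs: EnmoEpochSeries5s,
    window: DayWindow = DEFAULT_WINDOW,
    min_coverage: float = 0.75,
    *,
    participant_id: str = "",
    date: dt.date | None = None,
    sensor_position: str = "ankle",
) -> EnmoSlotSeries:
    """Aggregate 5-second epoch means onto the 15-minute slot grid.

    Slot mean is the unweighted mean of the present epoch means; coverage is
    the fraction of the expected epochs (180 for a 15-minute slot) present.
    """
    n_slots = window.n_slots
    expected = window.slot_s / EPOCH_SECONDS
    mean = np.full(n_slots, np.nan)
    cov = np.zeros(n_slots)

    if epochs.n_epochs:
        rel = epochs.epoch_start - window.start_s
        in_win = (rel >= 0) & (epochs.epoch_start < window.end_s)
        slot_idx = (rel[in_win] // window.slot_s).astype(int)
        vals = epochs.enmo_mean[in_win]
        counts = np.bincount(slot_idx, minlength=n_slots)
        sums = np.bincount(slot_idx, weights=vals, minlength=n_slots)
        present = counts > 0
        mean[present] = sums[present] / counts[present]
        cov = counts / expected

    valid = (cov >= min_coverage) & np.isfinite(mean)
    return EnmoSlotSeries(
        participant_id=participant_id,
        date=date or dt.date(1970, 1, 1),
        sensor_position=sensor_position,
        window=window,
        enmo_mean=mean,
        coverage=cov,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_raw_recording(path: str | Path, sampling_rate: float = 100.0) -> RawAccelRecording:
    """Read a ``<participant>_<date>_<position>.csv`` raw recording with
    header ``timestamp,ax,ay,az`` (ISO-8601 timestamps, g units)."""
    path = Path(path)
    stem_parts = path.stem.split("_")
    if len(stem_parts) < 3:
        raise DataError(f"raw file name {path.name!r} is not <participant>_<date>_<position>.csv")
    participant = stem_parts[0]
    date = dt.date.fromisoformat(stem_parts[1])
    position = "_".join(stem_parts[2:])

    df = pd.read_csv(path)
    required = {"timestamp", "ax", "ay", "az"}
    if not required.issubset(df.columns):
        raise DataError(f"{path.name}: missing columns {sorted(required - set(df.columns))}")
    ts = pd.to_datetime(df["timestamp"])
    dates = ts.dt.date.unique()
    if len(dates) > 1 or (len(dates) == 1 and dates[0] != date):
        raise DataError(f"{path.name}: timestamps do not all fall on {date}")
    seconds = (
        ts.dt.hour * 3600.0 + ts.dt.minute * 60.0 + ts.dt.second + ts.dt.microsecond / 1e6
    ).to_numpy()
    return RawAccelRecording(
        participant_id=participant,
        sensor_position=position,
        date=date,
        timestamps=seconds,
        ax=df["ax"].to_numpy(float),
        ay=df["ay"].to_numpy(float),
        az=df["az"].to_numpy(float),
        sampling_rate=sampling_rate,
    )


def write_epoch_csv(epochs: EnmoEpochSeries5s, path: str | Path) -> None:
    pd.DataFrame(
        {
            "epoch_start": epochs.epoch_start,
            "enmo_mean": epochs.enmo_mean,
            "n_samples": epochs.n_samples,
        }
    ).to_csv(path, index=False)


def read_epoch_csv(path: str | Path) -> EnmoEpochSeries5s:
    df = pd.read_csv(path)
    return EnmoEpochSeries5s(
        epoch_start=df["epoch_start"].to_numpy(float),
        enmo_mean=df["enmo_mean"].to_numpy(float),
        n_samples=df["n_samples"].to_numpy(int),
    )


def slot_series_frame(series: EnmoSlotSeries) -> pd.DataFrame:
    """Tidy one-row-per-slot frame:
    ``participant,date,position,slot_start,enmo_mean,coverage,valid``."""
    return pd.DataFrame(
        {
            "participant": series.participant_id,
            "date": series.date.isoformat(),
            "position": series.sensor_position,
            "slot_start": series.window.slot_labels(),
            "enmo_mean": series.enmo_mean,
            "coverage": series.coverage,
            "valid": series.valid,
        }
    )
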