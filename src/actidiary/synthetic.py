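"""Fully synthetic cohort generator with known ground truth.

The generator emits everything the pipeline ingests -- 5-second ENMO epoch
series (fast path) or raw 100 Hz tri-axial CSVs, activity diaries, a
matching Compendium table and participant metadata -- from a latent
activity schedule, so every downstream stage can be validated against
known truth without any external data.

Construction notes
------------------
Each participant-day is a piecewise schedule of blocks (1-4 slots) with a
latent intensity ``a`` in [0, 1] drawn from a discrete grid.  Active blocks
carry TWO parallel diary activities whose Compendium METs are
``rest + (max - rest) * a`` and ``rest + (max - rest) * low_ratio * a``, so
after joint min-max normalization the three slot MET levels are exactly
``(low_ratio * a, (1 + low_ratio)/2 * a, a)``.  The sensor ENMO target is
``scale * a ** (1/gain)``: a gain above 1 is a concave shape distortion
(not a pure multiplier, which min-max scaling would cancel) and yields the
systematically smaller fitted correction factors seen for wrist-worn
sensors.  Because both arms share the latent ``a`` and min-max
normalization pins both extremes, the recoverable ground-truth correction
factor is necessarily separable (level ratio x sensor shape factor); it is
computed from the latent schedule with the closed-form least-squares
formula and stored in :class:`GroundTruth`.
"""

from __future__ import annotations

import datetime as dt
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .signal_enmo import (
    EPOCH_SECONDS,
    EnmoEpochSeries5s,
    RawAccelRecording,
    SENSOR_POSITIONS,
    write_epoch_csv,
)
from .windows import DayWindow, DEFAULT_WINDOW

__all__ = ["SynthConfig", "GroundTruth", "SyntheticCohort", "synthesize_cohort", "synthesize_raw_segment"]

_A_GRID = np.round(np.arange(0.1, 1.01, 0.1), 1)
_GRID_WEIGHTS = np.array([0.22, 0.18, 0.14, 0.12, 0.10, 0.08, 0.06, 0.04, 0.03, 0.03])
_REST_LABEL = "resting"


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic cohort.

    ``sensor_gain`` is a shape exponent (wrist default > 1 emulates
    systematically higher wrist amplitudes); ``sensor_scale_g`` sets the raw
    ENMO amplitude in g.  ``noise_sd`` is additive Gaussian noise per
    5-second epoch on the normalized scale; ``wear_gap_rate`` is the
    per-slot probability of a wear gap; ``tremor_amplitude`` is an additive
    wrist component (normalized scale) applied to tremor participants.
    """

    n_participants: int = 25
    days_per_participant: int = 5
    window: DayWindow = DEFAULT_WINDOW
    start_date: dt.date = dt.date(2020, 3, 2)
    sensor_gain: tuple[float, float, float] = (1.0, 1.3, 1.0)  # ankle, wrist, lower_back
    sensor_scale_g: tuple[float, float, float] = (0.09, 0.12, 0.07)
    met_rest: float = 1.0
    met_max: float = 8.0
    level_ratio_low: float = 0.6
    rest_prob: float = 0.4
    noise_sd: float = 0.0
    wear_gap_rate: float = 0.0
    non_wear_rate: float = 0.0
    tremor_fraction: float = 0.0
    tremor_amplitude: float = 0.0
    tremor_freq_band: tuple[float, float] = (4.0, 6.0)
    margin_min: float = 30.0
    sampling_rate: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rest_prob", "wear_gap_rate", "non_wear_rate", "tremor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_participants < 1 or self.days_per_participant < 1:
            raise ConfigError("cohort dimensions must be positive")
        if not 0.0 < self.level_ratio_low <= 1.0:
            raise ConfigError("level_ratio_low must lie in (0, 1]")
        if self.met_max <= self.met_rest:
            raise ConfigError("met_max must exceed met_rest")
        if min(self.sensor_gain) <= 0 or min(self.sensor_scale_g) <= 0:
            raise ConfigError("sensor gains and scales must be positive")
        if self.noise_sd < 0 or self.tremor_amplitude < 0:
            raise ConfigError("noise_sd and tremor_amplitude must be nonnegative")

    @property
    def level_ratios(self) -> dict[str, float]:
        return {
            "low": self.level_ratio_low,
            "avg": (1.0 + self.level_ratio_low) / 2.0,
            "high": 1.0,
        }

    def gain(self, sensor: str) -> float:
        return self.sensor_gain[SENSOR_POSITIONS.index(sensor)]

    def scale(self, sensor: str) -> float:
        return self.sensor_scale_g[SENSOR_POSITIONS.index(sensor)]


@dataclass
class GroundTruth:
    """Latent truth emitted next to the bundle."""

    alpha_true: dict[str, float]  # "<sensor>/<level>" -> alpha
    level_ratios: dict[str, float]
    tremor_sums: dict[str, int]
    latent_a: dict[str, list[float]]  # "<pid>/<date>" -> 36 latent intensities
    sensor_gain: dict[str, float]
    sensor_scale_g: dict[str, float]

    def alpha(self, sensor: str, level: str) -> float:
        return self.alpha_true[f"{sensor}/{level}"]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticCohort:
    """In-memory bundle; ``write`` persists it as plain CSV/JSON files."""

    config: SynthConfig
    epochs: dict[tuple[str, str, str], EnmoEpochSeries5s]  # (pid, date_iso, sensor)
    diary: pd.DataFrame
    compendium: pd.DataFrame
    metadata: pd.DataFrame
    ground_truth: GroundTruth
    raw_recordings: dict[tuple[str, str, str], RawAccelRecording] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        try:
            (outdir / "enmo_5s").mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise DataError(f"cannot create output directory {outdir}: {exc}") from exc
        for (pid, date, sensor), series in sorted(self.epochs.items()):
            write_epoch_csv(series, outdir / "enmo_5s" / f"{pid}_{date}_{sensor}.csv")
        if self.raw_recordings:
            (outdir / "raw").mkdir(exist_ok=True)
            for (pid, date, sensor), rec in sorted(self.raw_recordings.items()):
                frame = pd.DataFrame(
                    {
                        "timestamp": [
                            f"{date}T{int(s) // 3600:02d}:{(int(s) % 3600) // 60:02d}:"
                            f"{s % 60:09.6f}"
                            for s in rec.timestamps
                        ],
                        "ax": rec.ax,
                        "ay": rec.ay,
                        "az": rec.az,
                    }
                )
                frame.to_csv(outdir / "raw" / f"{pid}_{date}_{sensor}.csv", index=False)
        self.diary.to_csv(outdir / "diary.csv", index=False)
        self.compendium.to_csv(outdir / "compendium.csv", index=False)
        self.metadata.to_csv(outdir / "metadata.csv", index=False)
        (outdir / "ground_truth.json").write_text(self.ground_truth.to_json())
        return outdir


def _participant_rng(seed: int, pid: str) -> np.random.Generator:
    # stable per-participant substream: hash the id, not Python's salted hash()
    return np.random.default_rng([seed, zlib.crc32(pid.encode())])


def _grid_level(a: float) -> int:
    return int(round(a * 10))


def _active_labels(a: float) -> tuple[str, str]:
    k = _grid_level(a)
    return f"active task {k}", f"light task {k}"


def _intensity_for(a: float) -> str:
    if a <= 0.3:
        return "mild"
    if a <= 0.7:
        return "moderate"
    return "vigorous"


def _build_compendium(cfg: SynthConfig) -> pd.DataFrame:
    rows = [{"activity": _REST_LABEL, "intensity": "any", "code": "07030", "met": cfg.met_rest}]
    span = cfg.met_max - cfg.met_rest
    for a in _A_GRID:
        k = _grid_level(a)
        hi, lo = _active_labels(a)
        for intensity in ("mild", "moderate", "vigorous"):
            rows.append(
                {"activity": hi, "intensity": intensity, "code": f"9{k:02d}1", "met": round(cfg.met_rest + span * a, 6)}
            )
            rows.append(
                {
                    "activity": lo,
                    "intensity": intensity,
                    "code": f"9{k:02d}2",
                    "met": round(cfg.met_rest + span * cfg.level_ratio_low * a, 6),
                }
            )
    return pd.DataFrame(rows)


def _schedule_day(
    rng: np.random.Generator,
    n_slots: int,
    rest_prob: float,
    forced: dict[int, float] | None = None,
) -> np.ndarray:
    """Latent intensity per slot as contiguous blocks of 1-4 slots."""
    a = np.zeros(n_slots)
    i = 0
    while i < n_slots:
        length = min(int(rng.integers(1, 5)), n_slots - i)
        val = 0.0 if rng.random() < rest_prob else float(rng.choice(_A_GRID, p=_GRID_WEIGHTS))
        a[i : i + length] = val
        i += length
    if forced:
        for slot, val in forced.items():
            a[slot] = val
    return a


def synthesize_raw_segment(
    target_enmo: float,
    duration_s: float,
    sampling_rate: float,
    rng: np.random.Generator,
    *,
    start_s: float = 0.0,
    tremor_amplitude_g: float = 0.0,
    tremor_freq_band: tuple[float, float] = (4.0, 6.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Tri-axial samples whose processed mean ENMO equals ``target_enmo``.

    The dynamic component is a band-limited oscillation on the vertical
    axis, ``az = 1 + pi * target * sin(2 pi f t)``: after norm-minus-one and
    truncation, the mean of the positive half-wave is exactly the target.
    The frequency is snapped so each 5-second epoch holds whole periods,
    keeping epoch means flat.  Returns ``(t, ax, ay, az)``.
    """
    if target_enmo < 0:
        raise DataError("target ENMO must be nonnegative")
    amplitude = np.pi * target_enmo
    if amplitude >= 1.0:
        raise DataError(f"target ENMO {target_enmo} g too large for the sinusoid construction")
    n = int(round(duration_s * sampling_rate))
    t = start_s + np.arange(n) / sampling_rate
    az = np.ones(n)
    if target_enmo > 0:
        f0 = rng.uniform(1.6, 3.2)
        f = max(0.2, round(f0 * EPOCH_SECONDS) / EPOCH_SECONDS)  # whole periods per 5 s
        az = az + amplitude * np.sin(2 * np.pi * f * (t - start_s))
    ax = np.zeros(n)
    if tremor_amplitude_g > 0:
        ft = rng.uniform(*tremor_freq_band)
        ax = ax + tremor_amplitude_g * np.sin(2 * np.pi * ft * (t - start_s))
    ay = np.zeros(n)
    return t, ax, ay, az


def synthesize_cohort(cfg: SynthConfig, *, raw: bool = False) -> SyntheticCohort:
    """Generate the full bundle; deterministic under ``cfg.rng_seed``.

    ``raw=True`` additionally emits 100 Hz raw recordings (expensive; meant
    for small configurations in signal-chain integration tests).
    """
    n_slots = cfg.window.n_slots
    pids = [f"P{i + 1:02d}" for i in range(cfg.n_participants)]
    dates = [cfg.start_date + dt.timedelta(days=d) for d in range(cfg.days_per_participant)]

    master = np.random.default_rng(cfg.rng_seed)
    n_tremor = int(round(cfg.tremor_fraction * cfg.n_participants))
    tremor_pids = set(master.choice(pids, size=n_tremor, replace=False)) if n_tremor else set()

    tremor_sums: dict[str, int] = {}
    metadata_rows = []
    for pid in pids:
        rng = _participant_rng(cfg.rng_seed, pid + "/meta")
        if pid in tremor_pids:
            items = rng.integers(1, 3, size=3)  # sum 3-6 -> stronger
        else:
            total = int(rng.integers(0, 2))  # 0 or 1 -> no/minimal
            items = np.zeros(3, dtype=int)
            if total:
                items[int(rng.integers(0, 3))] = 1
        tremor_sums[pid] = int(items.sum())
        metadata_rows.append(
            {
                "participant": pid,
                "updrs_3_15": int(items[0]),
                "updrs_3_16": int(items[1]),
                "updrs_3_17": int(items[2]),
            }
        )

    latent: dict[str, np.ndarray] = {}
    diary_rows: list[dict] = []
    epochs: dict[tuple[str, str, str], EnmoEpochSeries5s] = {}
    raw_recordings: dict[tuple[str, str, str], RawAccelRecording] = {}

    slot_starts = cfg.window.slot_starts
    epochs_per_slot = int(round(cfg.window.slot_s / EPOCH_SECONDS))
    margin_s = cfg.margin_min * 60.0

    for pid in pids:
        rng = _participant_rng(cfg.rng_seed, pid)
        for date in dates:
            date_iso = date.isoformat()
            # anchor the global extremes: first participant-day carries a
            # guaranteed rest slot and a full-intensity block mid-day
            if pid == pids[0] and date == dates[0]:
                mid = max(1, (n_slots * 5) // 9)
                forced = {0: 0.0, mid: 1.0, min(mid + 1, n_slots - 1): 1.0}
            else:
                forced = None
            a = _schedule_day(rng, n_slots, cfg.rest_prob, forced)
            latent[f"{pid}/{date_iso}"] = a

            non_wear_slots = np.zeros(n_slots, dtype=bool)
            # diary: walk blocks of constant latent intensity
            i = 0
            while i < n_slots:
                j = i
                while j < n_slots and a[j] == a[i]:
                    j += 1
                start_str = _hhmm(slot_starts[i])
                end_str = _hhmm(slot_starts[j - 1] + cfg.window.slot_s)
                if cfg.non_wear_rate > 0 and rng.random() < cfg.non_wear_rate:
                    non_wear_slots[i:j] = True
                    diary_rows.append(
                        _diary_row(pid, date_iso, start_str, end_str, "", "", non_wear=1)
                    )
                elif a[i] == 0.0:
                    diary_rows.append(
                        _diary_row(pid, date_iso, start_str, end_str, _REST_LABEL, "mild")
                    )
                else:
                    hi, lo = _active_labels(a[i])
                    intensity = _intensity_for(a[i])
                    diary_rows.append(_diary_row(pid, date_iso, start_str, end_str, hi, intensity))
                    diary_rows.append(_diary_row(pid, date_iso, start_str, end_str, lo, intensity))
                i = j

            # wear gaps: per slot, drop a contiguous run of 5-s epochs
            gap_mask = {}
            for s in range(n_slots):
                if cfg.wear_gap_rate > 0 and rng.random() < cfg.wear_gap_rate:
                    frac = rng.uniform(0.3, 1.0)
                    n_drop = int(round(frac * epochs_per_slot))
                    off = int(rng.integers(0, epochs_per_slot - n_drop + 1))
                    gap_mask[s] = (off, off + n_drop)

            tremor_here = pid in tremor_pids and cfg.tremor_amplitude > 0
            tremor_act = rng.uniform(0.3, 1.0, size=n_slots) if tremor_here else None

            for sensor in SENSOR_POSITIONS:
                scale, gain = cfg.scale(sensor), cfg.gain(sensor)
                slot_targets = scale * np.power(a, 1.0 / gain)
                if sensor == "wrist" and tremor_here:
                    slot_targets = slot_targets + cfg.tremor_amplitude * scale * tremor_act

                starts: list[np.ndarray] = []
                vals: list[np.ndarray] = []
                # leading/trailing margin at rest level keeps total covered
                # sensor time above the 9-hour rule even with wear gaps
                for lo_s, hi_s in (
                    (cfg.window.start_s - margin_s, cfg.window.start_s),
                    (cfg.window.end_s, cfg.window.end_s + margin_s),
                ):
                    n_m = int(round((hi_s - lo_s) / EPOCH_SECONDS))
                    if n_m > 0:
                        st = lo_s + EPOCH_SECONDS * np.arange(n_m)
                        v = np.zeros(n_m)
                        if cfg.noise_sd > 0:
                            v = v + scale * cfg.noise_sd * rng.standard_normal(n_m)
                        starts.append(st)
                        vals.append(np.maximum(v, 0.0))

                for s in range(n_slots):
                    st = slot_starts[s] + EPOCH_SECONDS * np.arange(epochs_per_slot)
                    v = np.full(epochs_per_slot, slot_targets[s])
                    if cfg.noise_sd > 0:
                        v = v + scale * cfg.noise_sd * rng.standard_normal(epochs_per_slot)
                    v = np.maximum(v, 0.0)
                    if s in gap_mask:
                        g0, g1 = gap_mask[s]
                        keep = np.ones(epochs_per_slot, dtype=bool)
                        keep[g0:g1] = False
                        st, v = st[keep], v[keep]
                    starts.append(st)
                    vals.append(v)

                all_starts = np.concatenate(starts)
                order = np.argsort(all_starts)
                series = EnmoEpochSeries5s(
                    epoch_start=all_starts[order],
                    enmo_mean=np.concatenate(vals)[order],
                    n_samples=np.full(all_starts.size, int(EPOCH_SECONDS * cfg.sampling_rate)),
                )
                epochs[(pid, date_iso, sensor)] = series

                if raw:
                    raw_recordings[(pid, date_iso, sensor)] = _raw_from_targets(
                        pid, date, sensor, series, cfg, rng
                    )

    gt = GroundTruth(
        alpha_true=_alpha_true(cfg, latent, pids, dates),
        level_ratios=cfg.level_ratios,
        tremor_sums=tremor_sums,
        latent_a={k: [float(x) for x in v] for k, v in latent.items()},
        sensor_gain={s: cfg.gain(s) for s in SENSOR_POSITIONS},
        sensor_scale_g={s: cfg.scale(s) for s in SENSOR_POSITIONS},
    )
    return SyntheticCohort(
        config=cfg,
        epochs=epochs,
        diary=pd.DataFrame(diary_rows),
        compendium=_build_compendium(cfg),
        metadata=pd.DataFrame(metadata_rows),
        ground_truth=gt,
        raw_recordings=raw_recordings,
    )


def _alpha_true(
    cfg: SynthConfig,
    latent: dict[str, np.ndarray],
    pids: list[str],
    dates: list[dt.date],
) -> dict[str, float]:
    """Recoverable correction factors from the latent schedule.

    Mirrors the pipeline's two-stage group averaging analytically:
    normalized MET is ``ratio * a``, normalized ENMO is ``a ** (1/gain)``,
    and the least-squares factor is ``sum(m * e) / sum(e^2)`` over slots.
    """
    a_bar = np.mean(
        [
            np.mean([latent[f"{pid}/{d.isoformat()}"] for d in dates], axis=0)
            for pid in pids
        ],
        axis=0,
    )
    out: dict[str, float] = {}
    for sensor in SENSOR_POSITIONS:
        e_bar = np.mean(
            [
                np.mean(
                    [np.power(latent[f"{pid}/{d.isoformat()}"], 1.0 / cfg.gain(sensor)) for d in dates],
                    axis=0,
                )
                for pid in pids
            ],
            axis=0,
        )
        shape = float(np.sum(a_bar * e_bar) / np.sum(e_bar * e_bar))
        for level, ratio in cfg.level_ratios.items():
            out[f"{sensor}/{level}"] = ratio * shape
    return out


def _raw_from_targets(
    pid: str,
    date: dt.date,
    sensor: str,
    series: EnmoEpochSeries5s,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> RawAccelRecording:
    ts, axs, ays, azs = [], [], [], []
    for start, target in zip(series.epoch_start, series.enmo_mean):
        t, ax, ay, az = synthesize_raw_segment(
            float(target), EPOCH_SECONDS, cfg.sampling_rate, rng, start_s=float(start)
        )
        ts.append(t)
        axs.append(ax)
        ays.append(ay)
        azs.append(az)
    return RawAccelRecording(
        participant_id=pid,
        sensor_position=sensor,
        date=date,
        timestamps=np.concatenate(ts),
        ax=np.concatenate(axs),
        ay=np.concatenate(ays),
        az=np.concatenate(azs),
        sampling_rate=cfg.sampling_rate,
    )


def _hhmm(sec: float) -> str:
    sec = int(round(sec))
    return f"{sec // 3600:02d}:{(sec % 3600) // 60:02d}"


def _diary_row(pid, date_iso, start, end, activity, intensity, non_wear=0) -> dict:
    return {
        "participant": pid,
        "date": date_iso,
        "start": start,
        "end": end,
        "activity": activity,
        "intensity": intensity,
        "non_wear": non_wear,
        "comment": "",
    }
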