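"""End-to-end orchestration: ENMO -> MET -> QC -> normalize -> fit -> report.

The pipeline consumes a bundle directory::

    <input_dir>/
      enmo_5s/<participant>_<date>_<position>.csv   (fast path)  OR
      raw/<participant>_<date>_<position>.csv       (100 Hz raw)
      diary.csv
      compendium.csv
      metadata.csv          (optional; needed for the tremor split)

and persists every intermediate as CSV plus a machine-readable
``run_summary.json`` and the resolved configuration.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import cohort_qc as qc
from . import diary_met as dm
from . import signal_enmo as se
from .config import PipelineConfig
from .errors import ConfigError, DataError, EmptyCohortError
from .windows import DayWindow

log = logging.getLogger(__name__)

STAGES = ("enmo", "mets", "qc", "fit", "report")

__all__ = [
    "RunArtifacts",
    "run_pipeline",
    "analyze_cohort",
    "write_reports",
    "validate_run_summary",
    "RUN_SUMMARY_REQUIRED",
]


@dataclass
class RunArtifacts:
    config: PipelineConfig
    enmo_days: dict[tuple[str, str, str], se.EnmoSlotSeries] = field(default_factory=dict)
    raw_spans: dict[tuple[str, str, str], se.RawDaySpan] = field(default_factory=dict)
    met_days: dict[tuple[str, str], dm.MetSlotSeries] = field(default_factory=dict)
    diary_rejects: pd.DataFrame = field(default_factory=pd.DataFrame)
    day_records: list[qc.DayRecord] = field(default_factory=list)
    panels: dict[tuple[str, str], qc.CohortPanel] = field(default_factory=dict)
    norm_params: dict[str, agr.NormalizationParams] = field(default_factory=dict)
    profiles: dict[tuple[str, str, str], agr.GroupProfile] = field(default_factory=dict)
    scalings: dict[tuple[str, str], agr.ScalingResult] = field(default_factory=dict)
    agreements: list[agr.SubjectAgreement] = field(default_factory=list)
    summary_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    tremor_table: pd.DataFrame | None = None
    run_summary: dict = field(default_factory=dict)


def _stage_guard(stage: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (DataError, EmptyCohortError) as exc:
                raise type(exc)(f"[stage {stage}] {exc}") from exc

        return inner

    return wrap


def run_pipeline(cfg: PipelineConfig, stop_after: str = "report") -> RunArtifacts:
    """Execute the stages in order, persisting intermediates as it goes.

    ``stop_after`` is one of ``enmo | mets | qc | fit | report``.  Any stage
    error aborts with the stage name prefixed to the message.
    """
    if stop_after not in STAGES:
        raise ConfigError(f"unknown stage {stop_after!r}; expected one of {STAGES}")
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    if not indir.is_dir():
        raise DataError(f"input directory {indir} does not exist")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(cfg.to_yaml())

    window = cfg.window.build()
    art = RunArtifacts(config=cfg)

    _run_enmo_stage(art, indir, outdir, window)
    if stop_after == "enmo":
        return art
    _run_met_stage(art, indir, outdir, window)
    if stop_after == "mets":
        return art
    _run_qc_stage(art, outdir)
    if stop_after == "qc":
        return art
    _run_fit_stage(art, outdir)
    if stop_after == "fit":
        return art
    write_reports(art, outdir, indir)
    return art


def analyze_cohort(bundle, cfg: PipelineConfig | None = None, **overrides) -> RunArtifacts:
    """Run the full analysis on an in-memory synthetic bundle, skipping all
    file IO.  ``overrides`` are keyword patches to the default
    :class:`PipelineConfig` (e.g. ``rules={"min_days": 2}``)."""
    if cfg is None:
        cfg = PipelineConfig(input_dir=".", output_dir=".", **overrides)
    window = cfg.window.build()
    art = RunArtifacts(config=cfg)

    for (pid, date_iso, sensor), epochs in sorted(bundle.epochs.items()):
        art.raw_spans[(pid, date_iso, sensor)] = se.RawDaySpan.from_epochs(epochs)
        art.enmo_days[(pid, date_iso, sensor)] = se.aggregate_slots(
            epochs,
            window,
            cfg.min_coverage,
            participant_id=pid,
            date=dt.date.fromisoformat(date_iso),
            sensor_position=sensor,
        )

    table = dm.CompendiumTable(bundle.compendium)
    entries, art.diary_rejects = dm.parse_diary(bundle.diary)
    grouped: dict[tuple[str, str], list[dm.DiaryEntry]] = {}
    for e in entries:
        grouped.setdefault((e.participant_id, e.date.isoformat()), []).append(e)
    for (pid, date_iso), day_entries in sorted(grouped.items()):
        art.met_days[(pid, date_iso)] = dm.diary_to_slots(
            day_entries, table, window, cfg.overlap_rule
        )

    _run_qc_stage(art, None)
    _run_fit_stage(art, None)
    art.summary_table = agr.summarize_rmse(art.agreements)

    labels = [
        agr.TremorLabel(pid, s) for pid, s in bundle.ground_truth.tremor_sums.items()
    ]
    positions = ("wrist", "lower_back") + (("ankle",) if cfg.tremor.include_ankle else ())
    present = tuple(p for p in positions if any(a.sensor_position == p for a in art.agreements))
    if present and labels:
        art.tremor_table = agr.tremor_split(labels, art.agreements, positions=present)
    return art


@_stage_guard("enmo")
def _run_enmo_stage(art: RunArtifacts, indir: Path, outdir: Path, window: DayWindow) -> None:
    filt = se.FilterConfig(
        order=art.config.filter.order,
        cutoff_hz=art.config.filter.cutoff_hz,
        placement=art.config.filter.placement,
    )
    epoch_files = sorted((indir / "enmo_5s").glob("*.csv")) if (indir / "enmo_5s").is_dir() else []
    raw_files = sorted((indir / "raw").glob("*.csv")) if (indir / "raw").is_dir() else []
    if not epoch_files and not raw_files:
        raise DataError(f"no enmo_5s/ or raw/ recordings found under {indir}")

    frames = []
    seen = set()
    for path in epoch_files + raw_files:
        pid, date_iso, position = _parse_bundle_name(path)
        if (pid, date_iso, position) in seen:
            continue  # epoch file takes precedence over raw duplicate
        seen.add((pid, date_iso, position))
        if path in epoch_files:
            epochs = se.read_epoch_csv(path)
        else:
            raw = se.read_raw_recording(path, sampling_rate=art.config.sampling_rate)
            samples = se.compute_enmo(raw, filt)
            epochs = se.aggregate_5s(samples, raw.sampling_rate)
        span = se.RawDaySpan.from_epochs(epochs)
        slots = se.aggregate_slots(
            epochs,
            window,
            art.config.min_coverage,
            participant_id=pid,
            date=dt.date.fromisoformat(date_iso),
            sensor_position=position,
        )
        art.enmo_days[(pid, date_iso, position)] = slots
        art.raw_spans[(pid, date_iso, position)] = span
        frames.append(se.slot_series_frame(slots))
    pd.concat(frames, ignore_index=True).to_csv(outdir / "enmo_slots.csv", index=False)


@_stage_guard("mets")
def _run_met_stage(art: RunArtifacts, indir: Path, outdir: Path, window: DayWindow) -> None:
    diary_path = indir / "diary.csv"
    if not diary_path.exists():
        raise DataError(f"missing diary.csv under {indir}")
    comp_path = indir / "compendium.csv"
    table = dm.CompendiumTable.from_csv(comp_path) if comp_path.exists() else dm.load_bundled_compendium()

    entries, rejects = dm.parse_diary(pd.read_csv(diary_path))
    art.diary_rejects = rejects
    if len(rejects):
        rejects.to_csv(outdir / "diary_rejects.csv", index=False)

    grouped: dict[tuple[str, str], list[dm.DiaryEntry]] = {}
    for e in entries:
        grouped.setdefault((e.participant_id, e.date.isoformat()), []).append(e)

    frames = []
    for (pid, date_iso), day_entries in sorted(grouped.items()):
        series = dm.diary_to_slots(day_entries, table, window, art.config.overlap_rule)
        art.met_days[(pid, date_iso)] = series
        frames.append(dm.met_series_frame(series))
    if not frames:
        raise DataError("diary produced no parseable entries")
    pd.concat(frames, ignore_index=True).to_csv(outdir / "met_slots.csv", index=False)


@_stage_guard("qc")
def _run_qc_stage(art: RunArtifacts, outdir: Path | None) -> None:
    cfg = art.config
    rules = qc.InclusionRules(
        min_simultaneous_slots=cfg.rules.min_simultaneous_slots,
        min_days=cfg.rules.min_days,
        min_sensor_hours=cfg.rules.min_sensor_hours,
        require_window_span=cfg.rules.require_window_span,
        sensor_hours_mode=cfg.rules.sensor_hours_mode,
    )
    window = cfg.window.build()
    for (pid, date_iso, position), enmo_day in sorted(art.enmo_days.items()):
        met_day = art.met_days.get((pid, date_iso))
        if met_day is None:
            met_day = _empty_met_day(pid, date_iso, window)
        art.day_records.append(
            qc.validate_day(enmo_day, met_day, art.raw_spans[(pid, date_iso, position)], rules)
        )
    if outdir is not None:
        qc.qc_report_frame(art.day_records).to_csv(outdir / "qc_report.csv", index=False)

    positions = sorted({r.sensor_position for r in art.day_records})
    for position in positions:
        for level in agr.MET_LEVELS:
            art.panels[(position, level)] = qc.build_cohort(
                art.day_records, position, level, min_days=rules.min_days
            )
    if outdir is not None:
        summary = qc.cohort_summary(art.panels, art.day_records)
        (outdir / "cohort_summary.json").write_text(json.dumps(summary, indent=2))


def _empty_met_day(pid: str, date_iso: str, window: DayWindow) -> dm.MetSlotSeries:
    n = window.n_slots
    return dm.MetSlotSeries(
        participant_id=pid,
        date=dt.date.fromisoformat(date_iso),
        window=window,
        met_low=np.full(n, np.nan),
        met_avg=np.full(n, np.nan),
        met_high=np.full(n, np.nan),
        n_activities=np.zeros(n, dtype=int),
        valid=np.zeros(n, dtype=bool),
        non_wear=np.zeros(n, dtype=bool),
        n_entries=0,
    )


@_stage_guard("fit")
def _run_fit_stage(art: RunArtifacts, outdir: Path | None) -> None:
    cfg = art.config
    normalized, params = agr.normalize_panels(art.panels)
    art.panels = normalized
    art.norm_params = params
    opt = agr.OptimizerConfig(
        xatol=cfg.optimizer.xatol, fatol=cfg.optimizer.fatol, maxiter=cfg.optimizer.maxiter
    )
    rows = []
    for (sensor, level), panel in sorted(normalized.items()):
        ge = agr.group_profile(panel, "enmo", two_stage=cfg.two_stage_profile)
        gm = agr.group_profile(panel, "met", two_stage=cfg.two_stage_profile)
        art.profiles[(sensor, level, "enmo")] = ge
        art.profiles[(sensor, level, "met")] = gm
        scaling = agr.fit_alpha(ge, gm, opt, sensor_position=sensor, met_level=level)
        art.scalings[(sensor, level)] = scaling
        rows.append(
            {
                "sensor": sensor,
                "met_level": level,
                "alpha": scaling.alpha,
                "init_alpha": scaling.init_alpha,
                "fit_rmse": scaling.fit_rmse,
                "n_slots": scaling.n_slots_used,
                "converged": scaling.converged,
            }
        )
        art.agreements.extend(
            agr.subject_rmse(panel, scaling, per_day_average=cfg.subject_rmse_per_day_average)
        )
    if outdir is not None:
        pd.DataFrame(rows).to_csv(outdir / "scaling_results.csv", index=False)
        pd.DataFrame(
            {
                "participant": [a.participant_id for a in art.agreements],
                "sensor": [a.sensor_position for a in art.agreements],
                "met_level": [a.met_level for a in art.agreements],
                "rmse": [a.rmse for a in art.agreements],
                "n_epochs": [a.n_epochs for a in art.agreements],
            }
        ).to_csv(outdir / "subject_rmse.csv", index=False)


def write_reports(art: RunArtifacts, outdir: Path, indir: Path) -> None:
    """Summary tables, per-slot profiles, tremor stratification and
    ``run_summary.json``; optional plots."""
    art.summary_table = agr.summarize_rmse(art.agreements)
    art.summary_table.to_csv(outdir / "summary_table1.csv", index=False)

    window = art.config.window.build()
    prof_rows = []
    for (sensor, level, arm), prof in sorted(art.profiles.items()):
        for slot, label in enumerate(window.slot_labels()):
            prof_rows.append(
                {
                    "sensor": sensor,
                    "met_level": level,
                    "arm": arm,
                    "slot_start": label,
                    "mean": prof.mean[slot],
                    "sd": prof.sd[slot],
                    "n_participants": prof.n_participants[slot],
                }
            )
    pd.DataFrame(prof_rows).to_csv(outdir / "group_profiles.csv", index=False)

    meta_path = indir / "metadata.csv"
    if meta_path.exists():
        labels = read_tremor_labels(meta_path)
        positions = ("wrist", "lower_back") + (("ankle",) if art.config.tremor.include_ankle else ())
        present = tuple(p for p in positions if any(a.sensor_position == p for a in art.agreements))
        if present:
            art.tremor_table = agr.tremor_split(labels, art.agreements, positions=present)
            art.tremor_table.to_csv(outdir / "tremor_summary.csv", index=False)

    included = [r for r in art.day_records if r.included]
    art.run_summary = {
        "n_participants": len({r.participant_id for r in included}),
        "n_days_included": len(included),
        "n_days_excluded": len(art.day_records) - len(included),
        "n_epochs": int(sum(p.total_epochs for (s, l), p in art.panels.items() if l == "avg")),
        "alphas": {f"{s}/{l}": sc.alpha for (s, l), sc in sorted(art.scalings.items())},
        "fit_rmse": {f"{s}/{l}": sc.fit_rmse for (s, l), sc in sorted(art.scalings.items())},
        "normalization": {
            k: {"min": p.observed_min, "max": p.observed_max, "degenerate": p.degenerate}
            for k, p in sorted(art.norm_params.items())
        },
        "n_diary_rejects": int(len(art.diary_rejects)),
        "n_unmapped_entries": int(sum(m.n_unmapped for m in art.met_days.values())),
    }
    validate_run_summary(art.run_summary)
    (outdir / "run_summary.json").write_text(json.dumps(art.run_summary, indent=2))

    if art.config.plots:
        from . import plots

        plots.plot_group_profiles(art, outdir / "fig_profiles.png")
        plots.plot_rmse_boxes(art, outdir / "fig_rmse_boxes.png")


RUN_SUMMARY_REQUIRED = {
    "n_participants": int,
    "n_days_included": int,
    "n_days_excluded": int,
    "n_epochs": int,
    "alphas": dict,
    "fit_rmse": dict,
    "normalization": dict,
    "n_diary_rejects": int,
    "n_unmapped_entries": int,
}


def validate_run_summary(payload: dict) -> None:
    """Check the run summary against its published schema."""
    for key, typ in RUN_SUMMARY_REQUIRED.items():
        if key not in payload:
            raise DataError(f"run summary missing key {key!r}")
        if not isinstance(payload[key], typ):
            raise DataError(f"run summary key {key!r} must be {typ.__name__}")
    for name, value in payload["alphas"].items():
        if not isinstance(value, (int, float)) or not np.isfinite(value):
            raise DataError(f"non-finite alpha for {name!r}")


def read_tremor_labels(path: str | Path) -> list[agr.TremorLabel]:
    """Metadata CSV: ``participant,updrs_3_15,updrs_3_16,updrs_3_17`` (or a
    pre-summed ``tremor_sum`` column)."""
    df = pd.read_csv(path)
    if "tremor_sum" in df.columns:
        sums = df["tremor_sum"].astype(int)
    else:
        cols = ["updrs_3_15", "updrs_3_16", "updrs_3_17"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DataError(f"metadata missing columns {missing}")
        sums = df[cols].sum(axis=1).astype(int)
    return [
        agr.TremorLabel(participant_id=str(p), tremor_sum=int(s))
        for p, s in zip(df["participant"], sums)
    ]


def _parse_bundle_name(path: Path) -> tuple[str, str, str]:
    parts = path.stem.split("_")
    if len(parts) < 3:
        raise DataError(f"file name {path.name!r} is not <participant>_<date>_<position>.csv")
    return parts[0], parts[1], "_".join(parts[2:])
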