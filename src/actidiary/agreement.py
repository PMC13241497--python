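"""Min-max normalization, linear correction fit and agreement metrics.

The two arms are first min-max normalized to [0, 1] using global extremes:
separately per sensor position for ENMO, jointly across the three intensity
levels for MET.  Residual amplitude mismatch is then absorbed by a single
multiplicative correction factor per sensor x level, fitted by Nelder-Mead
on the group-mean profiles under the model ``met = alpha * enmo``.
Individual agreement is the per-participant RMSE of the corrected signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort_qc import CohortPanel
from .errors import DataError

log = logging.getLogger(__name__)

MET_LEVELS = ("low", "avg", "high")
NORMALIZATION_EPS = 1e-9

__all__ = [
    "NormalizationParams",
    "OptimizerConfig",
    "GroupProfile",
    "ScalingResult",
    "SubjectAgreement",
    "TremorLabel",
    "fit_minmax",
    "apply_minmax",
    "normalize_panels",
    "group_profile",
    "alpha_closed_form",
    "fit_alpha",
    "subject_rmse",
    "summarize_rmse",
    "tremor_split",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Global min-max transform; ``degenerate`` when max == min, in which
    case the transform maps everything to zero."""

    observed_min: float
    observed_max: float
    degenerate: bool = False


def fit_minmax(values: np.ndarray) -> NormalizationParams:
    """Fit global min/max over all finite values of one scope."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise DataError("cannot fit min-max normalization on no finite values")
    vmin, vmax = float(finite.min()), float(finite.max())
    degenerate = vmax - vmin <= NORMALIZATION_EPS
    if degenerate:
        warnings.warn("degenerate min-max scope (max == min); transform maps to 0", stacklevel=2)
    return NormalizationParams(observed_min=vmin, observed_max=vmax, degenerate=degenerate)


def apply_minmax(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if params.degenerate:
        out = np.zeros_like(values)
        out[~np.isfinite(values)] = np.nan
        return out
    return (values - params.observed_min) / (params.observed_max - params.observed_min)


def normalize_panels(
    panels: dict[tuple[str, str], CohortPanel],
) -> tuple[dict[tuple[str, str], CohortPanel], dict[str, NormalizationParams]]:
    """Normalize all panels in place of raw units.

    ENMO uses one transform per sensor position (fitted across all subjects,
    days and daytime slots of that sensor's panels); MET uses a single
    shared transform across all levels.  Returns the normalized panels and
    the fitted parameter set keyed ``enmo/<sensor>`` and ``met``.
    """
    sensors = sorted({s for s, _ in panels})
    params: dict[str, NormalizationParams] = {}
    for sensor in sensors:
        vals = np.concatenate(
            [p.enmo_values() for (s, _), p in panels.items() if s == sensor] or [np.empty(0)]
        )
        params[f"enmo/{sensor}"] = fit_minmax(vals)
    met_vals = np.concatenate([p.met_values() for p in panels.values()] or [np.empty(0)])
    params["met"] = fit_minmax(met_vals)

    normalized: dict[tuple[str, str], CohortPanel] = {}
    for (sensor, level), panel in panels.items():
        ep = params[f"enmo/{sensor}"]
        mp = params["met"]
        norm = panel.transformed(
            enmo_fn=lambda a, ep=ep: apply_minmax(a, ep),
            met_fn=lambda a, mp=mp: apply_minmax(a, mp),
        )
        _assert_unit_interval(norm)
        normalized[(sensor, level)] = norm
    return normalized, params


def _assert_unit_interval(panel: CohortPanel) -> None:
    for arr in (panel.enmo_values(), panel.met_values()):
        if arr.size and (arr.min() < -NORMALIZATION_EPS or arr.max() > 1 + NORMALIZATION_EPS):
            raise AssertionError("normalized panel values escaped [0, 1]")


@dataclass
class GroupProfile:
    """Per-slot group mean and SD across participants (each participant is
    first averaged across their included days)."""

    mean: np.ndarray
    sd: np.ndarray
    n_participants: np.ndarray

    def present(self) -> np.ndarray:
        return np.isfinite(self.mean)


def group_profile(
    panel: CohortPanel,
    arm: str = "enmo",
    *,
    two_stage: bool = True,
    sd_single: float = 0.0,
) -> GroupProfile:
    """Two-stage group profile: within-participant mean across days per
    slot, then mean and sample SD across participants.

    ``two_stage=False`` pools all participant-days in a single stage.
    Slots with no contributing participant are NaN.
    """
    if arm not in ("enmo", "met"):
        raise DataError(f"unknown arm: {arm!r}")
    n = panel.n_slots
    rows = []
    for pid, days in panel.participants.items():
        stack = np.vstack([getattr(d, arm) for d in days])
        if two_stage:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slots
                rows.append(np.nanmean(stack, axis=0))
        else:
            rows.extend(stack)
    mat = np.vstack(rows) if rows else np.full((0, n), np.nan)

    counts = np.isfinite(mat).sum(axis=0)
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        has = counts > 0
        mean[has] = np.nanmean(mat[:, has], axis=0)
        multi = counts > 1
        sd[multi] = np.nanstd(mat[:, multi], axis=0, ddof=1)
    sd[counts == 1] = sd_single
    return GroupProfile(mean=mean, sd=sd, n_participants=counts)


def _joint_slots(group_enmo: GroupProfile, group_met: GroupProfile) -> tuple[np.ndarray, np.ndarray]:
    mask = group_enmo.present() & group_met.present()
    return group_enmo.mean[mask], group_met.mean[mask]


def alpha_closed_form(group_enmo: GroupProfile, group_met: GroupProfile) -> float:
    """Analytic least-squares minimizer of RMSE for ``met = alpha * enmo``:
    ``alpha* = sum(M*E) / sum(E^2)`` over jointly present slots."""
    e, m = _joint_slots(group_enmo, group_met)
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise DataError("closed-form alpha undefined: all group-mean ENMO values are zero")
    return float(np.sum(m * e) / denom)


@dataclass(frozen=True)
class OptimizerConfig:
    """Nelder-Mead settings; None leaves SciPy's defaults in place.

    The package defaults are tighter than SciPy's so the fitted factor
    agrees with the analytic least-squares minimizer to 1e-6; pass
    ``OptimizerConfig(None, None)`` explicitly for SciPy's own defaults.
    """

    xatol: float | None = 1e-10
    fatol: float | None = 1e-12
    maxiter: int | None = None


@dataclass
class ScalingResult:
    sensor_position: str
    met_level: str
    alpha: float
    fit_rmse: float
    init_alpha: float
    converged: bool
    n_slots_used: int


def fit_alpha(
    group_enmo: GroupProfile,
    group_met: GroupProfile,
    optimizer_cfg: OptimizerConfig = OptimizerConfig(),
    *,
    sensor_position: str = "",
    met_level: str = "",
) -> ScalingResult:
    """Fit the correction factor by minimizing the RMSE between the
    group-mean profiles with Nelder-Mead, initialized at the ratio of the
    two profile averages."""
    e, m = _joint_slots(group_enmo, group_met)
    if e.size < 2:
        raise DataError(f"need at least 2 jointly present slots to fit alpha (got {e.size})")
    mean_e = float(np.mean(e))
    if mean_e == 0.0:
        raise DataError("cannot initialize alpha: group-mean ENMO averages to zero")
    init = float(np.mean(m)) / mean_e

    def rmse(a: np.ndarray) -> float:
        return float(np.sqrt(np.mean((a[0] * e - m) ** 2)))

    options: dict = {}
    if optimizer_cfg.xatol is not None:
        options["xatol"] = optimizer_cfg.xatol
    if optimizer_cfg.fatol is not None:
        options["fatol"] = optimizer_cfg.fatol
    if optimizer_cfg.maxiter is not None:
        options["maxiter"] = optimizer_cfg.maxiter
    res = optimize.minimize(rmse, x0=[init], method="Nelder-Mead", options=options)
    if not res.success:
        warnings.warn(f"Nelder-Mead did not converge for {sensor_position}/{met_level}", stacklevel=2)
    return ScalingResult(
        sensor_position=sensor_position,
        met_level=met_level,
        alpha=float(res.x[0]),
        fit_rmse=float(res.fun),
        init_alpha=init,
        converged=bool(res.success),
        n_slots_used=int(e.size),
    )


@dataclass
class SubjectAgreement:
    participant_id: str
    sensor_position: str
    met_level: str
    rmse: float
    n_epochs: int


def subject_rmse(
    panel: CohortPanel,
    scaling: ScalingResult,
    *,
    per_day_average: bool = False,
) -> list[SubjectAgreement]:
    """Per-participant RMSE of the corrected normalized ENMO against the
    normalized MET, pooling all joint epochs across included days.

    ``per_day_average=True`` instead averages per-day RMSE values.  The
    corrected signal is clipped at 0 but deliberately not at 1.
    """
    if (scaling.sensor_position, scaling.met_level) != (panel.sensor_position, panel.met_level):
        raise DataError(
            f"scaling fitted for {scaling.sensor_position}/{scaling.met_level} applied "
            f"to panel {panel.sensor_position}/{panel.met_level}"
        )
    out: list[SubjectAgreement] = []
    for pid, days in panel.participants.items():
        day_sq: list[np.ndarray] = []
        for d in days:
            e, m = d.enmo[d.mask], d.met[d.mask]
            corrected = np.maximum(scaling.alpha * e, 0.0)
            day_sq.append((corrected - m) ** 2)
        n = int(sum(sq.size for sq in day_sq))
        if n == 0:
            warnings.warn(f"participant {pid} has zero joint epochs; excluded", stacklevel=2)
            continue
        if per_day_average:
            rmse = float(np.mean([np.sqrt(np.mean(sq)) for sq in day_sq if sq.size]))
        else:
            rmse = float(np.sqrt(np.mean(np.concatenate(day_sq))))
        out.append(
            SubjectAgreement(
                participant_id=pid,
                sensor_position=panel.sensor_position,
                met_level=panel.met_level,
                rmse=rmse,
                n_epochs=n,
            )
        )
    return out


def summarize_rmse(agreements: list[SubjectAgreement]) -> pd.DataFrame:
    """Median / min / max of the subject RMSE distribution per sensor x MET
    level (even-count median uses the midpoint convention)."""
    if not agreements:
        raise DataError("no agreements to summarize")
    df = pd.DataFrame(
        {
            "sensor": [a.sensor_position for a in agreements],
            "met_level": [a.met_level for a in agreements],
            "rmse": [a.rmse for a in agreements],
        }
    )
    out = (
        df.groupby(["met_level", "sensor"], sort=True)["rmse"]
        .agg(median="median", min="min", max="max", n="count")
        .reset_index()
    )
    return out


@dataclass(frozen=True)
class TremorLabel:
    """Sum of the three tremor items (0-12) on the most-affected side;
    <= 1 defines the no/minimal-tremor group."""

    participant_id: str
    tremor_sum: int

    def __post_init__(self) -> None:
        if not 0 <= self.tremor_sum <= 12:
            raise DataError(f"tremor sum {self.tremor_sum} out of range 0-12")

    @property
    def group(self) -> str:
        return "no_minimal" if self.tremor_sum <= 1 else "stronger"


def tremor_split(
    labels: list[TremorLabel],
    agreements: list[SubjectAgreement],
    positions: tuple[str, ...] = ("wrist", "lower_back"),
) -> pd.DataFrame:
    """RMSE summaries stratified by tremor subgroup, restricted to the
    given sensor positions (ankle off by default)."""
    by_pid = {lab.participant_id: lab.group for lab in labels}
    missing = sorted({a.participant_id for a in agreements} - set(by_pid))
    if missing:
        raise DataError(f"unlabeled participants in tremor split: {missing}")
    frames = []
    for grp in ("no_minimal", "stronger"):
        subset = [
            a for a in agreements if by_pid[a.participant_id] == grp and a.sensor_position in positions
        ]
        if not subset:
            continue
        summary = summarize_rmse(subset)
        summary.insert(0, "tremor_group", grp)
        frames.append(summary)
    if not frames:
        raise DataError("tremor split produced no strata")
    return pd.concat(frames, ignore_index=True)
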