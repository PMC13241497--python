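"""Optional figures: mean +/- SD ribbons per slot and RMSE box plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

SENSOR_COLORS = {"ankle": "tab:blue", "wrist": "tab:red", "lower_back": "tab:green"}


def plot_group_profiles(art, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = sorted({lvl for (_, lvl, _) in art.profiles})
    fig, axes = plt.subplots(1, len(levels), figsize=(5 * len(levels), 4), sharey=True)
    axes = np.atleast_1d(axes)
    window = art.config.window.build()
    x = np.arange(window.n_slots)
    for ax, level in zip(axes, levels):
        for (sensor, lvl, arm), prof in art.profiles.items():
            if lvl != level:
                continue
            if arm == "enmo":
                scaling = art.scalings[(sensor, level)]
                mean = scaling.alpha * prof.mean
                sd = abs(scaling.alpha) * prof.sd
                ax.plot(x, mean, color=SENSOR_COLORS.get(sensor, "gray"), label=sensor)
                ax.fill_between(x, mean - sd, mean + sd, color=SENSOR_COLORS.get(sensor, "gray"), alpha=0.15)
            else:
                ax.plot(x, prof.mean, "k--", lw=1, label=f"MET {level}" if sensor == "ankle" else None)
        ax.set_title(f"{level} MET")
        ax.set_xlabel("15-min slot (09:00-18:00)")
    axes[0].set_ylabel("normalized intensity")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rmse_boxes(art, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = sorted({a.met_level for a in art.agreements})
    sensors = sorted({a.sensor_position for a in art.agreements})
    fig, axes = plt.subplots(1, len(levels), figsize=(4 * len(levels), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, level in zip(axes, levels):
        data = [
            [a.rmse for a in art.agreements if a.met_level == level and a.sensor_position == s]
            for s in sensors
        ]
        bp = ax.boxplot(data, tick_labels=sensors, patch_artist=True, flierprops={"markerfacecolor": "gray"})
        for patch, s in zip(bp["boxes"], sensors):
            patch.set_facecolor(SENSOR_COLORS.get(s, "gray"))
            patch.set_alpha(0.4)
        ax.set_title(f"{level} MET")
    axes[0].set_ylabel("subject RMSE (normalized)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
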