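"""Diagnostic figures: method-comparison scatter and daily trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def equality_scatter(panel: pd.DataFrame, path, level: str | None = None) -> None:
    """Sensor vs self-report scatter with the line of equality."""
    level = level or panel.attrs.get("level", "")
    fig, ax = plt.subplots(figsize=(5, 5))
    for pid, g in panel.groupby("participant_id"):
        ax.scatter(g["sensor"], g["selfreport"], s=14, alpha=0.6, label=pid)
    lim = max(panel["sensor"].max(), panel["selfreport"].max(), 1.0) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--", label="equality")
    ax.set_xlabel("sensor")
    ax.set_ylabel("self-report")
    ax.set_title(f"Agreement at level: {level}")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    if panel["participant_id"].nunique() <= 12:
        ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def trajectory_plot(sensor: dict, selfreport: dict, path) -> None:
    """Per-participant daily wear trajectories, sensor and self-report."""
    pids = sorted(set(sensor) & set(selfreport))
    n = len(pids)
    fig, axes = plt.subplots(n, 1, figsize=(8, 1.6 * n), sharex=True, squeeze=False)
    for ax, pid in zip(axes.ravel(), pids):
        s, r = sensor[pid].minutes, selfreport[pid].minutes
        ax.plot(s.index, s.values, lw=1, label="sensor")
        ax.plot(r.index, r.values, lw=1, ls="--", label="self-report")
        ax.set_ylabel(pid, fontsize=7)
        ax.tick_params(labelsize=6)
    axes.ravel()[0].legend(fontsize=6)
    fig.suptitle("Daily wear minutes by participant")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
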