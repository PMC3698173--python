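"""Matplotlib figures from saved trajectories and sweep tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .io import read_trajectory

__all__ = ["plot_trajectories", "plot_sweep", "plot_polymerization"]


def plot_trajectories(paths: list[str | Path], out: str | Path) -> Path:
    """Centrosome speed and displacement vs time for one or more runs."""
    fig, (ax_v, ax_x) = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
    for path in paths:
        traj = read_trajectory(path)
        minutes = traj.times / 60.0
        ax_v.plot(minutes, traj.centrosome_speeds * 1000.0, label=Path(path).stem)
        ax_x.plot(minutes, traj.displacements)
    ax_v.set_ylabel("centrosome speed (nm/s)")
    ax_v.legend(fontsize=8)
    ax_x.axhline(300.0, color="grey", ls="--", lw=0.8)
    ax_x.set_xlabel("time (min)")
    ax_x.set_ylabel("displacement toward centre (µm)")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def _mean_sd(table: pd.DataFrame, by: str, metric: str):
    g = table.groupby(by)[metric]
    return g.mean(), g.std()


def plot_sweep(table_path: str | Path, vary: str, out: str | Path) -> Path:
    """Mean ± sd of centring time (or displacement) against the swept value."""
    table = pd.read_csv(table_path)
    metric = (
        "centering_time_s"
        if table["centering_time_s"].notna().any()
        else "displacement_45min_um"
    )
    mean, sd = _mean_sd(table, vary, metric)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(mean.index, mean / 60.0 if metric.endswith("_s") else mean,
                yerr=(sd / 60.0 if metric.endswith("_s") else sd), marker="o")
    ax.set_xlabel(vary)
    ax.set_ylabel("centering time (min)" if metric.endswith("_s") else "displacement (µm)")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_polymerization(table_path: str | Path, out: str | Path) -> Path:
    """Centring time vs polymerization rate, marking far-wall contact ordering."""
    table = pd.read_csv(table_path)
    mean, sd = _mean_sd(table, "polymerization_rate", "centering_time_s")
    touch = table.groupby("polymerization_rate")["far_touch_before_centering"].mean()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(mean.index * 1000.0, mean / 60.0, yerr=sd / 60.0, marker="o")
    for rate, frac in touch.items():
        ax.annotate(
            f"{frac:.0%} touch first",
            (rate * 1000.0, mean[rate] / 60.0),
            textcoords="offset points",
            xytext=(4, 6),
            fontsize=7,
        )
    ax.set_xlabel("polymerization rate (nm/s)")
    ax.set_ylabel("centering time (min)")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
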