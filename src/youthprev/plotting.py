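"""Matplotlib rendering of sensitivity surfaces and trajectories."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_grid_heatmap", "plot_effect_curves", "plot_trajectory"]

_KIND_COLOURS = {"universal": "0.4", "selective": "tab:blue", "indicated": "tab:red"}


def plot_grid_heatmap(grid: pd.DataFrame, path: str | Path) -> None:
    """Heatmap of post-intervention prevalence over the (phi, theta) plane."""
    pivot = grid.pivot_table(index="theta", columns="phi", values="prevalence")
    fig, ax = plt.subplots(figsize=(6, 4.5))
    mesh = ax.pcolormesh(
        pivot.columns, pivot.index, 100 * pivot.values, cmap="YlOrRd", shading="auto"
    )
    fig.colorbar(mesh, ax=ax, label="equilibrium prevalence of disorders (%)")
    ax.set_xlabel(r"$\phi$ (proportion vulnerable at entry)")
    ax.set_ylabel(r"$\theta$ (onset hazard ratio)")
    ax.set_title(f"Selective intervention, h = {grid['h_post'].iloc[0]:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_effect_curves(curves: pd.DataFrame, path: str | Path,
                       title: str = "") -> None:
    """Prevalence vs individual-level effect, one line per intervention type."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for kind, sub in curves.groupby("kind", sort=False):
        ax.plot(sub["effect"], 100 * sub["prevalence"], label=kind,
                color=_KIND_COLOURS.get(kind))
    ax.set_xlabel("individual-level intervention effect")
    ax.set_ylabel("equilibrium prevalence of disorders (%)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trajectory(frame: pd.DataFrame, path: str | Path,
                    switch_time: float | None = None) -> None:
    """Disorder prevalence over time for a transient intervention scenario."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(frame["time"], 100 * frame["prevalence_D"])
    if switch_time is not None:
        ax.axvline(switch_time, ls="--", color="0.6", lw=1)
    ax.set_xlabel("time (years)")
    ax.set_ylabel("prevalence of disorders (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
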