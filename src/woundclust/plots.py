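"""Matplotlib adapters for the standard figures.

Each adapter draws from the same tidy tables the pipeline writes to disk, so
figures are a rendering of exported data, never a separate computation.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_pair_scatter", "plot_cluster_series", "plot_trajectory"]

HIGHLIGHT_COLORS = {"epithelial": "red", "muscle": "blue"}


def plot_pair_scatter(scatter: pd.DataFrame, title: str = "", path=None):
    """Edge-vs-center expression scatter for one wound pair, axes [0, 20]."""
    fig, ax = plt.subplots(figsize=(4, 4))
    plain = scatter[scatter["highlight"] == ""]
    ax.plot(plain["edge"], plain["center"], ".", color="0.6", ms=2)
    for name, grp in scatter[scatter["highlight"] != ""].groupby("highlight"):
        ax.plot(
            grp["edge"], grp["center"], ".", ms=4,
            color=HIGHLIGHT_COLORS.get(name, "green"), label=name,
        )
    ax.plot([0, 20], [0, 20], "-", color="0.8", lw=0.5)
    ax.set(xlim=(0, 20), ylim=(0, 20), xlabel="edge log2(1+expr)",
           ylabel="center log2(1+expr)", title=title)
    if scatter["highlight"].ne("").any():
        ax.legend(fontsize=7)
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_cluster_series(summary: pd.DataFrame, title: str = "", path=None):
    """Per-day mean +/- sd of a mean-cluster series, edge vs center."""
    fig, ax = plt.subplots(figsize=(5, 3))
    colors = {"edge": "black", "center": "red"}
    for loc, grp in summary.groupby("location"):
        grp = grp.sort_values("day")
        ax.errorbar(grp["day"], grp["mean"], yerr=grp["sd"], color=colors.get(loc),
                    label=loc, marker="o", ms=3, capsize=2)
    ax.set(xlabel="day", ylabel="mean cluster value C", title=title)
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_trajectory(traj: pd.DataFrame, labels=("A", "B"), path=None):
    """Healing path in a cluster-cluster plane, day-0 and final-day markers."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    colors = {"edge": "black", "center": "red"}
    for loc, grp in traj.groupby("location"):
        grp = grp.sort_values("day")
        ax.plot(grp["a"], grp["b"], "-o", ms=3, color=colors.get(loc), label=loc)
        end = grp[grp["is_end"]]
        ax.plot(end["a"], end["b"], "*", ms=12, color="green")
    start = traj[traj["is_start"]].iloc[:1]
    ax.plot(start["a"], start["b"], "*", ms=14, color="blue")
    ax.set(xlabel=labels[0], ylabel=labels[1])
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
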