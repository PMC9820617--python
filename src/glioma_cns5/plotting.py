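"""Basic plots: Kaplan-Meier curves per group and a consensus-matrix heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["plot_km_by_group", "plot_consensus_heatmap"]


def plot_km_by_group(groups: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """One KM curve per survival group (frame with group/time/event columns)."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, sub in groups.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=f"{label} (n={len(sub)})")
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_consensus_heatmap(consensus: pd.DataFrame, assignment: pd.Series, path: str | Path) -> None:
    order = assignment.sort_values(kind="stable").index
    mat = consensus.loc[order, order].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="co-clustering frequency")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"consensus matrix (k={assignment.nunique()})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
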