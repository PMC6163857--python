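"""Trajectory plots with the harvest-threshold line."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd


def plot_trajectories(
    trajectories: pd.DataFrame,
    threshold: float = 0.8,
    path: Union[str, Path, None] = None,
    title: str = "",
):
    """Plot per-well OD trajectories (true OD as lines, readings as dots).

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for well, g in trajectories.groupby("well", sort=False):
        g = g.sort_values("t")
        ax.plot(g["t"], g["true_od"], lw=1, alpha=0.7, label=well)
        meas = g.dropna(subset=["reported_od"])
        ax.plot(meas["t"], meas["reported_od"], "o", ms=3, alpha=0.7)
    ax.axhline(threshold, color="red", lw=1.2, label="harvest threshold")
    ax.set_xlabel("time [h]")
    ax.set_ylabel("OD600")
    if title:
        ax.set_title(title)
    if len(trajectories["well"].unique()) <= 8:
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
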