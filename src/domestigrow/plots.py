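"""The two diagnostic figures: reaction norms and the performance-ratio scatter.

Requires matplotlib (the ``plot`` extra); everything else in the package works
without it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_GROUP_COLORS = {"farm": "#d62728", "hybrid": "#7f7f7f", "wild": "#1f77b4"}


def plot_reaction_norms(norms: pd.DataFrame, ax=None):
    """Family reaction norms (log10 weight, control -> stress), colored by group."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    for r in norms.itertuples(index=False):
        ax.plot([0, 1], [r.control, r.stress], color=_GROUP_COLORS.get(r.group, "k"),
                alpha=0.7, lw=1)
    ax.set_xticks([0, 1], ["control", "stress"])
    ax.set_ylabel("mean log10 weight (g)")
    handles = [plt.Line2D([], [], color=c, label=g) for g, c in _GROUP_COLORS.items()]
    ax.legend(handles=handles, frameon=False)
    return ax


def plot_performance_ratio(points: pd.DataFrame, null_points: pd.DataFrame | None = None,
                           ax=None):
    """Performance ratio vs control weight per group, with per-group regression
    lines; optionally overlays the simulated null cloud."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    if null_points is not None:
        ax.scatter(null_points["y"], null_points["ratio"], s=6, c="lightgray",
                   label="simulated null")
    for g, sub in points.groupby("group"):
        c = _GROUP_COLORS.get(g, "k")
        ax.scatter(sub["y"], sub["ratio"], s=14, c=c, label=g)
        if len(sub) >= 3:
            b, a = np.polyfit(sub["y"], sub["ratio"], 1)
            xs = np.linspace(sub["y"].min(), sub["y"].max(), 20)
            ax.plot(xs, a + b * xs, c=c, lw=1)
    ax.set_xlabel("family mean weight, control tank (g)")
    ax.set_ylabel("performance ratio (log x / log y)")
    ax.legend(frameon=False)
    return ax
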