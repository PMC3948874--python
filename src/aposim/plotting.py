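"""Minimal plot helpers for the standard analyses (matplotlib)."""

from __future__ import annotations

import numpy as np

SERIES_COLORS = {
    "non-poisonous": "tab:blue",
    "mimic": "tab:orange",
    "poisonous": "tab:pink",
    "predator": "0.4",
}


def plot_avoidance_curve(results, band=None, outcomes=None, ax=None):
    """Fitted avoidance probability vs poison level, with optional bootstrap
    band and per-level observed frequencies."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(results.grid, results.curve, "k-", label="fit")
    if band is not None:
        ax.plot(band.grid, band.lower, "r--", lw=1)
        ax.plot(band.grid, band.upper, "r--", lw=1, label="95% bootstrap CI")
    if outcomes is not None:
        from .analysis import outcomes_to_frame

        df = outcomes_to_frame(outcomes)
        g = df.groupby("poison_level")["under_pressure"].agg(["size", "sum"])
        ax.plot(g.index, 1.0 - g["sum"] / g["size"], "o", mfc="none", mec="k",
                label="observed")
    ax.set_xlabel("poison level")
    ax.set_ylabel("P(predators avoid poisonous prey)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_trajectories(summary, ax=None):
    """Mean population trajectories with bootstrap bands (tidy frame from
    :func:`aposim.analysis.trajectory_summary`)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, g in summary.groupby("series"):
        c = SERIES_COLORS.get(name, None)
        ax.plot(g["update"], g["mean"], color=c, label=name)
        ax.fill_between(g["update"], g["lower"], g["upper"], color=c, alpha=0.25, lw=0)
    ax.set_xlabel("update")
    ax.set_ylabel("abundance")
    ax.legend(frameon=False)
    return ax


def plot_display_proportions(props, ax=None):
    """Mimic display-proportion series (frame from
    :func:`aposim.analysis.mimic_display_proportions`)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = {
        "displays_non_poisonous": ("non-poisonous", "tab:blue"),
        "displays_mimic": ("mimic", "tab:orange"),
        "displays_poisonous": ("poisonous", "tab:pink"),
    }
    for col, (label, color) in labels.items():
        ax.plot(props["update"], props[col], color=color, label=f"displays {label}")
    ax.set_xlabel("update")
    ax.set_ylabel("proportion of mimic class")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    return ax
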