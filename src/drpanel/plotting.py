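"""Thin matplotlib layer over the tabular outputs.

The CSV tables are the contract; these helpers render the three
standard displays (waterfall plot, bias/replicability grid, power
curve) for quick inspection.  Each function returns the figure.
"""

from __future__ import annotations

import numpy as np


def plot_waterfall(waterfall, scale: str = "md", ax=None):
    """Strains ordered by their no-pooling estimate, with the shrunken
    partial-pooling estimates overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    cols = (
        ("md_none", "md_partial", "MD (days)")
        if scale == "md"
        else ("lnhr_none", "lnhr_partial", "lnHR")
    )
    none_col, partial_col, ylabel = cols
    if none_col not in waterfall.columns:
        none_col, partial_col = "no_pooling", "partial_pooling"
    order = waterfall.sort_values(none_col, ascending=False)
    xs = np.arange(len(order))
    ax.bar(xs, order[none_col], color="0.3", label="no pooling")
    if partial_col in order.columns:
        ax.plot(xs, order[partial_col], "o", color="tab:blue",
                label="partial pooling", markersize=4)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("strain (ordered by no-pooling estimate)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return ax.figure


def plot_bias_grid(cells, ax=None):
    """Median estimated CV_G (points, with IQR bars) and replicability
    (crosses) against per-arm sample size, one panel per true CV_G."""
    import matplotlib.pyplot as plt

    cells = cells.copy()
    cv_levels = sorted(cells["true_cv_g"].unique())
    fig, axes = plt.subplots(
        1, len(cv_levels), figsize=(3.2 * len(cv_levels), 3.2), sharey=True
    )
    axes = np.atleast_1d(axes)
    colors = {"none": "0.2", "partial": "tab:blue"}
    for ax_i, cv in zip(axes, cv_levels):
        sub = cells[cells["true_cv_g"] == cv]
        for est, grp in sub.groupby("estimator"):
            pooling = est.split("-")[1]
            c = colors[pooling]
            ls = "-" if est.startswith("lnhr") else "--"
            grp = grp.sort_values("n_per_arm")
            ax_i.errorbar(
                grp["n_per_arm"], grp["cvg_median"],
                yerr=grp["cvg_iqr"] / 2, fmt="o" + ls, color=c, ms=4,
                label=est, capsize=2,
            )
            ax_i.plot(grp["n_per_arm"], grp["replicability"], "x" + ls,
                      color=c, alpha=0.6)
        ax_i.axhline(cv, color="r", lw=0.6, ls=":")
        ax_i.set_title(f"true CV_G = {cv:g}")
        ax_i.set_xlabel("animals per strain per diet")
    axes[0].set_ylabel("estimated CV_G / replicability")
    axes[0].legend(frameon=False, fontsize=7)
    fig.tight_layout()
    return fig


def plot_power_curve(power_table, alpha: float = 0.05, target: float = 0.8, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    t = power_table.sort_values("n_per_arm")
    ax.errorbar(t["n_per_arm"], t["power"], yerr=t["binomial_se"],
                fmt="o-", capsize=2)
    ax.axhline(target, color="r", ls=":", lw=0.8)
    ax.axhline(alpha, color="0.5", ls=":", lw=0.8)
    ax.set_xlabel("animals per strain per diet")
    ax.set_ylabel("power of variance LRT")
    ax.set_ylim(0, 1.02)
    return ax.figure
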