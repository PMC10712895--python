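"""Publication-style plots: thick seed-mean over translucent per-seed curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

__all__ = ["plot_metric_series", "plot_experiment"]


def plot_metric_series(arm_result, ax=None, color=None, label=None):
    """Envelope projection area over time for one experiment arm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    times = arm_result.series["time"]
    line = None
    for col in arm_result.series.columns:
        if col == "time":
            continue
        (line,) = ax.plot(times, arm_result.series[col], alpha=0.25, lw=0.8, color=color)
    ax.plot(
        arm_result.aggregate["time"],
        arm_result.aggregate["mean"],
        lw=2.2,
        color=line.get_color() if line is not None else color,
        label=label or arm_result.label,
    )
    ax.set_xlabel("time (a.u.)")
    ax.set_ylabel("envelope projection area (d$^2$)")
    return ax


def plot_experiment(result, path=None):
    """All arms of one experiment on a shared axis; optionally save to file."""
    _, ax = plt.subplots(figsize=(5.5, 3.8))
    for arm in result.arms:
        plot_metric_series(arm, ax=ax)
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(result.name)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
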