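"""Simple report figures (optional; requires matplotlib).

Two plot kinds mirror the standard presentation of this analysis:
per-bin group mean +/- SEM overlays with significance ticks, and DF
bar charts (mean +/- SEM per group).
"""

from __future__ import annotations

import numpy as np

from .records import N_BINS
from .stats import BinwiseComparison


def plot_binwise(comp: BinwiseComparison, ax=None):
    """Mean +/- SEM of both groups per cycle bin, significant bins ticked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    bins = np.arange(1, N_BINS + 1)
    for mean, sem, label in (
        (comp.mean_a, comp.sem_a, comp.group_a),
        (comp.mean_b, comp.sem_b, comp.group_b),
    ):
        ax.plot(bins, mean, label=label)
        ax.fill_between(bins, mean - sem, mean + sem, alpha=0.25)
    sig = bins[comp.significant]
    if len(sig):
        y0 = min((comp.mean_a - comp.sem_a).min(), (comp.mean_b - comp.sem_b).min())
        ax.plot(sig, np.full(len(sig), y0), "k*", markersize=4)
    ax.set_xlabel("step cycle (%)")
    ax.set_ylabel(f"{comp.axis} displacement (AU)")
    ax.set_title(
        f"{comp.joint} {comp.side}: {comp.group_a} vs {comp.group_b} "
        f"({comp.percent_changed}% of cycle changed)"
    )
    ax.legend(frameon=False)
    return ax


def plot_df_bars(distributions: dict[str, np.ndarray], title: str = "", ax=None):
    """Mean +/- SEM bar per group DF distribution."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    groups = list(distributions)
    means = [np.mean(distributions[g]) for g in groups]
    sems = [
        np.std(distributions[g], ddof=1) / np.sqrt(len(distributions[g]))
        for g in groups
    ]
    ax.bar(groups, means, yerr=sems, capsize=3)
    ax.set_ylabel("DF (AU$^2$)")
    if title:
        ax.set_title(title)
    return ax
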