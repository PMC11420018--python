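"""Figures: centrality profile and the three-panel ESA scenario plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .esa import ESAProfile
from .items import STRATEGIES


def plot_centrality(centralities: pd.DataFrame, path) -> None:
    """Z-scored strength and bridge strength per node, nodes on the y-axis."""
    cols = [c for c in ("strength_z", "bridge_strength_z") if c in centralities]
    fig, axes = plt.subplots(1, len(cols), figsize=(3.2 * len(cols), 6), sharey=True)
    if len(cols) == 1:
        axes = [axes]
    order = centralities.index[::-1]
    for ax, col in zip(axes, cols):
        ax.plot(centralities.loc[order, col], range(len(order)), "o-", ms=4)
        ax.set_yticks(range(len(order)))
        ax.set_yticklabels(order, fontsize=7)
        ax.set_title(col.replace("_z", ""), fontsize=10)
        ax.axvline(0, color="gray", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_esa_scenarios(profiles: list[ESAProfile], path) -> None:
    """One panel per scenario: ESA vs conditioned sum-score for each strategy,
    with the baseline as a horizontal reference line."""
    scenarios = sorted({p.scenario for p in profiles}, key=["minimum", "median", "maximum"].index)
    fig, axes = plt.subplots(1, len(scenarios), figsize=(4.2 * len(scenarios), 3.6), sharey=True)
    if len(scenarios) == 1:
        axes = [axes]
    for ax, scenario in zip(axes, scenarios):
        for strategy in STRATEGIES:
            match = [p for p in profiles if p.scenario == scenario and p.strategy == strategy]
            if match:
                ax.plot(match[0].grid, match[0].esa_values, label=strategy, lw=1.2)
        baseline = next(p.baseline_esa for p in profiles if p.scenario == scenario)
        ax.axhline(baseline, color="gray", lw=1, ls="--", label="baseline")
        ax.set_title(f"{scenario} background", fontsize=10)
        ax.set_xlabel("conditioned sum-score")
    axes[0].set_ylabel("expected symptom activity")
    axes[-1].legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
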