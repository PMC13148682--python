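"""Optional figures: reliability heatmaps and permutation null histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .permutation import PermutationResult


def plot_reliability_heatmap(
    reliability: pd.DataFrame, metric: str, path: str | Path | None = None
):
    """Network-by-condition heatmap of clamped ICCs for one metric."""
    sub = reliability[reliability["metric"] == metric]
    pivot = sub.pivot_table(index="network", columns="condition", values="icc")
    fig, ax = plt.subplots(figsize=(1.2 * pivot.shape[1] + 2, 0.4 * pivot.shape[0] + 2))
    im = ax.imshow(pivot.to_numpy(), vmin=0, vmax=1, cmap="viridis", aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.set_title(f"ICC(3,1), {metric}")
    fig.colorbar(im, ax=ax, label="ICC")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_null_distribution(
    result: PermutationResult, null: np.ndarray | None = None,
    path: str | Path | None = None,
):
    """Null band (2.5/97.5 percentiles) with the observed ICC difference."""
    fig, ax = plt.subplots(figsize=(5, 3))
    if null is not None:
        ax.hist(null, bins=40, color="0.8", density=True)
    for q in (result.null_q025, result.null_q975):
        ax.axvline(q, color="tab:blue", ls="--", label="95% null band")
    ax.axvline(result.observed_diff, color="tab:red", label="observed")
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), fontsize=8)
    ax.set_xlabel(f"ICC({result.condition_a}) - ICC({result.condition_b})")
    ax.set_title(f"{result.network} / {result.metric}  p={result.p_value:.3g}",
                 fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
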