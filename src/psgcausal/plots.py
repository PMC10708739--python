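"""Figure helpers: link-frequency heatmaps and covariate box plots."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .cohort import CohortResult  # noqa: E402


def plot_heatmap(result: CohortResult, path: str | Path | None = None,
                 title: str | None = None):
    """Heatmap of link identification fractions; consensus links ticked."""
    d = result.heatmap.shape[0]
    names = result.channel_names or [f"ch{i}" for i in range(d)]
    fig, ax = plt.subplots(figsize=(0.6 * d + 2, 0.6 * d + 2))
    im = ax.imshow(result.heatmap, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(d), names, rotation=90)
    ax.set_yticks(range(d), names)
    ax.set_xlabel("source (cause)")
    ax.set_ylabel("target (effect)")
    for x in range(d):
        for y in range(d):
            if result.consensus[x, y]:
                ax.text(y, x, "✓", ha="center", va="center", color="w")
    fig.colorbar(im, ax=ax, label="fraction of windows with link")
    ax.set_title(title or f"{result.method}: link frequency")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_link_boxplot(box_data: pd.DataFrame, covariate: str,
                      link_label: str = "", path: str | Path | None = None):
    """Box plot of per-subject link counts across covariate quantile bins."""
    bins = sorted(box_data["bin"].unique())
    groups = [box_data.loc[box_data["bin"] == b, "count"].to_numpy()
              for b in bins]
    fig, ax = plt.subplots(figsize=(1.5 * len(bins) + 2, 4))
    ax.boxplot(groups, tick_labels=bins)
    ax.set_xlabel(f"{covariate} (quantile bins)")
    ax.set_ylabel("windows with link")
    ax.set_title(link_label)
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_cv_table(table: pd.DataFrame, path: str | Path | None = None):
    """Heatmap of cross-validated RMSE over the penalty grid."""
    pivot = table.pivot(index="lambda_a", columns="lambda_w", values="rmse")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(pivot.to_numpy(), cmap="magma")
    ax.set_xticks(range(pivot.shape[1]), [f"{v:g}" for v in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]), [f"{v:g}" for v in pivot.index])
    ax.set_xlabel("lambda_W")
    ax.set_ylabel("lambda_A")
    fig.colorbar(im, ax=ax, label="held-out RMSE")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
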