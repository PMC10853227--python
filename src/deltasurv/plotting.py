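"""Matplotlib figures for strategy results."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_cindex_heatmap", "plot_shap_importance", "plot_medoid_consistency"]


def plot_cindex_heatmap(frame: pd.DataFrame, ax=None, title: str = "Test C-index"):
    """Selector x regressor heatmap of mean test C-indices."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * frame.shape[1] + 2, 0.8 * frame.shape[0] + 1.5))
    im = ax.imshow(frame.to_numpy(), cmap="viridis", vmin=0.4, vmax=0.9)
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=30, ha="right")
    ax.set_yticks(range(frame.shape[0]), frame.index)
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            v = frame.iat[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", color="white")
    ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_shap_importance(ranking: pd.DataFrame, top: int = 10, ax=None):
    """Horizontal bar chart of mean |SHAP| per feature."""
    import matplotlib.pyplot as plt

    sub = ranking.head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(sub) + 1.5))
    ax.barh(sub["feature"], sub["mean_abs_shap"], color="#4472a8")
    ax.set_xlabel("mean |SHAP|")
    ax.set_title("Feature importance")
    ax.figure.tight_layout()
    return ax


def plot_medoid_consistency(report, ax=None):
    """Per-cluster medoid-consistency percentages across CV folds."""
    import matplotlib.pyplot as plt

    frame = report.medoid_consistency.sort_values("consistency_pct")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(frame) + 1.5))
    ax.barh(frame["medoid"], frame["consistency_pct"], color="#6aa36a")
    ax.axvline(80, color="k", ls="--", lw=1)
    ax.set_xlabel("% of folds with the same medoid")
    ax.set_xlim(0, 100)
    ax.set_title(f"Medoid consistency (mean pairwise ARI {report.mean_pairwise_ari:.2f})")
    ax.figure.tight_layout()
    return ax
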