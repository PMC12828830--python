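"""Figure helpers for the run report (volcano, ROC, forest)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "sphingoquant"  # deterministic SVG ids
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["volcano_plot", "roc_plot", "forest_plot"]


def volcano_plot(stats_df: pd.DataFrame, path, p_adj_threshold: float = 0.01) -> None:
    """Volcano of per-species log2FC vs −log10 p, significant species in
    orange (up) / light blue (down)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = stats_df["p_adj"] < p_adj_threshold
    up = sig & (stats_df["log2fc"] > 0)
    dn = sig & (stats_df["log2fc"] < 0)
    ax.scatter(stats_df["log2fc"], -np.log10(stats_df["p"]), s=8, c="0.7", label="n.s.")
    ax.scatter(stats_df.loc[up, "log2fc"], -np.log10(stats_df.loc[up, "p"]), s=10, c="tab:orange")
    ax.scatter(stats_df.loc[dn, "log2fc"], -np.log10(stats_df.loc[dn, "p"]), s=10, c="lightblue")
    ax.set_xlabel("log2 fold change (case / control)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def roc_plot(scores_by_model: dict, labels_by_model: dict, path) -> None:
    """Empirical ROC curves, one per model."""
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, scores in scores_by_model.items():
        fpr, tpr, _ = roc_curve(labels_by_model[name], scores)
        ax.plot(fpr, tpr, label=name)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def forest_plot(forest: pd.DataFrame, path, title: str = "") -> None:
    """Forest rendering of per-study and pooled effects with 95% CIs."""
    fig, ax = plt.subplots(figsize=(5, 0.35 * len(forest) + 1))
    y = np.arange(len(forest))[::-1]
    for i, (_, row) in enumerate(forest.iterrows()):
        pooled = i == len(forest) - 1
        ax.plot([row["ci_low"], row["ci_high"]], [y[i], y[i]], "k-", lw=1.6 if pooled else 0.9)
        ax.plot(
            row["log2fc"], y[i],
            "D" if pooled else "s",
            color="tab:red" if pooled else "k",
            ms=6 if pooled else max(2.5, row["weight_pct"] / 12),
        )
    ax.axvline(0, color="0.6", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(forest["row"], fontsize=7)
    ax.set_xlabel("log2 fold change")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
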