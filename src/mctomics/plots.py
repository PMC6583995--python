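"""Basic figure exports: the two-group expression heatmap and the
module-trait correlation matrix."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .expression import SampleClustering

__all__ = ["expression_heatmap", "module_trait_heatmap"]


def expression_heatmap(
    expr: pd.DataFrame,
    tree: SampleClustering | None = None,
    risk: pd.Series | None = None,
    path=None,
):
    """Gene x sample heatmap on the log scale, samples in dendrogram order.

    ``risk`` (sample -> 'high'/'low') draws the grey group bar along the top.
    Returns the matplotlib figure; writes to ``path`` when given.
    """
    order = tree.leaf_order if tree is not None else list(expr.columns)
    data = expr[order].to_numpy()
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(order)), 6))
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{expr.shape[0]} genes")
    fig.colorbar(im, ax=ax, shrink=0.6, label="log expression")
    if risk is not None:
        colours = ["0.2" if risk[s] == "high" else "0.8" for s in order]
        for i, c in enumerate(colours):
            ax.add_patch(plt.Rectangle((i - 0.5, -0.02 * data.shape[0] - 1), 1, 1,
                                       color=c, clip_on=False))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def module_trait_heatmap(module_trait: pd.DataFrame, path=None):
    """One-column matrix of module-trait correlations, annotated 'r (p)'."""
    mt = module_trait.set_index("module")
    fig, ax = plt.subplots(figsize=(3, max(2, 0.4 * len(mt))))
    vals = mt[["r"]].to_numpy()
    im = ax.imshow(vals, cmap="RdYlGn_r", vmin=-1, vmax=1, aspect="auto")
    for i, (r, p) in enumerate(zip(mt["r"], mt["p"])):
        ax.text(0, i, f"{r:+.2f}\n({p:.2g})", ha="center", va="center", fontsize=8)
    ax.set_yticks(range(len(mt)))
    ax.set_yticklabels(mt.index)
    ax.set_xticks([0])
    ax.set_xticklabels(["malignancy score"])
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
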