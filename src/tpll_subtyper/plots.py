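"""Minimal figure exports: a clustered expression heatmap and
Kaplan–Meier step curves.  Deliberately plain — tables are the primary
output format; these are quick-look exports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import leaves_list

from .core_io import ExpressionMatrix
from .subgroup_discovery import ClusterTree
from .survival import SurvivalCurve


def save_expression_heatmap(matrix: ExpressionMatrix, tree: ClusterTree,
                            path, max_genes: int = 500) -> None:
    """Row-z-scored heatmap with samples in dendrogram leaf order.

    At most ``max_genes`` of the highest-variance genes are drawn."""
    order = leaves_list(tree.linkage)
    arr = matrix.values.to_numpy()
    if arr.shape[0] > max_genes:
        keep = np.argsort(arr.var(axis=1))[-max_genes:]
        arr = arr[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / (
        arr.std(axis=1, keepdims=True) + 1e-12)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(z[:, order], aspect="auto", cmap="RdBu_r",
                   vmin=-3, vmax=3, interpolation="nearest")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels([tree.sample_ids[i] for i in order],
                       rotation=90, fontsize=4)
    ax.set_yticks([])
    ax.set_xlabel("samples (dendrogram order)")
    ax.set_ylabel("genes (z-scored)")
    fig.colorbar(im, ax=ax, shrink=0.6, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_km_curves(curves: dict[str, SurvivalCurve], path,
                   time_label: str = "days from diagnosis") -> None:
    """Step plot of one Kaplan–Meier curve per group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=str(name))
        if curve.censor_times.size:
            at = [curve.survival_at(ct) for ct in curve.censor_times]
            ax.plot(curve.censor_times, at, "|", color=ax.lines[-1].get_color())
    ax.set_xlabel(time_label)
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
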