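"""Heatmap exports: association matrix and reordered module heatmap."""

from __future__ import annotations

import numpy as np

from .association import AssociationResult
from .data import LFCMatrix
from .modules import InteractingModule, reorder_for_heatmap

__all__ = ["plot_association_heatmap", "plot_module_heatmap", "plot_scree"]


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_association_heatmap(result: AssociationResult, path) -> None:
    """Coefficient matrix with significant cells outlined in black."""
    plt = _plt()
    k, l = result.shape
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * l), max(3, 0.4 * k)))
    vmax = np.abs(result.coefficients).max() or 1.0
    im = ax.imshow(
        result.coefficients, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
        aspect="auto",
    )
    for i, j in np.argwhere(result.significant):
        ax.add_patch(
            plt.Rectangle(
                (j - 0.5, i - 0.5), 1, 1, fill=False, edgecolor="black",
                linewidth=1.5,
            )
        )
    ax.set_xlabel("gene IC")
    ax.set_ylabel("condition IC")
    fig.colorbar(im, ax=ax, label="regression coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_module_heatmap(
    M: LFCMatrix,
    modules: list[InteractingModule],
    path,
    max_genes: int | None = None,
) -> None:
    """Reordered LFC matrix with module blocks outlined.

    ``max_genes`` truncates the display to the first rows of the reordered
    matrix (module members come first by construction).
    """
    plt = _plt()
    gene_order, cond_order, annotations = reorder_for_heatmap(M, modules)
    if max_genes is not None:
        gene_order = gene_order[:max_genes]
    gi = [M.gene_index(g) for g in gene_order]
    ci = [M.condition_index(c) for c in cond_order]
    block = M.values[np.ix_(gi, ci)]
    fig, ax = plt.subplots(
        figsize=(max(5, 0.15 * len(ci)), max(4, 0.01 * len(gi)))
    )
    vmax = np.percentile(np.abs(block), 99) or 1.0
    im = ax.imshow(block, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    for ann in annotations:
        r0, r1 = ann["row_span"]
        c0, c1 = ann["col_span"]
        if max_genes is not None and r0 >= len(gene_order):
            continue
        ax.add_patch(
            plt.Rectangle(
                (c0 - 0.5, r0 - 0.5), c1 - c0 + 1, r1 - r0 + 1,
                fill=False, edgecolor="black", linewidth=1.2,
            )
        )
    ax.set_xlabel("conditions (module order)")
    ax.set_ylabel("genes (module order)")
    fig.colorbar(im, ax=ax, label="LFC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scree(scree, chosen: int | None, path) -> None:
    """Aggregate K^2 versus component count, with the chosen r marked."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(scree.r_grid, scree.metric, marker="o")
    if chosen is not None:
        ax.axvline(chosen, color="red", linestyle="--", label=f"r = {chosen}")
        ax.legend()
    ax.set_xlabel("number of components r")
    ax.set_ylabel("sum of component K$^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
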