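"""Static figure export: ranked dot plot, comparison heatmap, volcano plot."""

from __future__ import annotations

import numpy as np

from .hitcall import ComparisonMatrix, rank_plot_table


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_rank(records, cutoff: float, ax=None):
    """Interaction intensities sorted in increasing order; hits in red."""
    ax = _get_ax(ax)
    table = rank_plot_table(records)
    hit = table["is_interactor"].fillna(False).to_numpy(dtype=bool)
    ax.scatter(table["rank"][~hit], table["normalized_score"][~hit],
               s=6, c="0.6", label="non-interactor")
    ax.scatter(table["rank"][hit], table["normalized_score"][hit],
               s=10, c="crimson", label="interactor")
    ax.axhline(cutoff, ls=":", c="k", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("protein rank")
    ax.set_ylabel("normalized interaction intensity")
    ax.legend(frameon=False, fontsize="small")
    return ax


def plot_comparison_heatmap(matrix: ComparisonMatrix, ax=None):
    """log10 normalized scores, proteins x RNAs, in matrix row order."""
    ax = _get_ax(ax)
    values = np.log10(matrix.scores.to_numpy(dtype=float))
    im = ax.imshow(values, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(matrix.rna_ids)), matrix.rna_ids)
    ax.set_ylabel(f"{len(matrix.protein_ids)} proteins")
    ax.figure.colorbar(im, ax=ax, label="log10 normalized intensity")
    return ax


def plot_volcano(enrichment_table, ax=None):
    """Domain occurrence among hits vs -log10 p; enriched domains in blue."""
    ax = _get_ax(ax)
    t = enrichment_table
    neglog = -np.log10(np.clip(t["p_raw"].to_numpy(dtype=float), 1e-300, None))
    flagged = t["enriched"].to_numpy(dtype=bool)
    ax.scatter(t["k_hits"][~flagged], neglog[~flagged], s=10, c="0.6")
    ax.scatter(t["k_hits"][flagged], neglog[flagged], s=14, c="tab:blue")
    ax.set_xlabel("interactors carrying domain")
    ax.set_ylabel("-log10(P)")
    return ax
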