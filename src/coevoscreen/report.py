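"""Presence/absence distribution reports (gene x genome maps)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["presence_absence_report", "plot_presence_absence"]


def presence_absence_report(
    matrix: pd.DataFrame, genes: Sequence[str]
) -> pd.DataFrame:
    """Distribution map of a gene subset across genomes.

    Genomes (canonical tree order, as carried by the matrix columns)
    become rows; the selected genes become columns.  Mirrors the classic
    figure layout of a taxon-by-gene presence map.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene subset")
    unknown = [g for g in genes if g not in matrix.index]
    if unknown:
        raise KeyError(f"unknown gene(s): {unknown}")
    return matrix.loc[genes].T


def plot_presence_absence(report: pd.DataFrame, path: str | Path) -> None:
    """Render the distribution map as filled/empty cells (optional plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_genomes, n_genes = report.shape
    fig_h = max(2.0, 0.12 * n_genomes)
    fig_w = max(2.0, 0.4 * n_genes)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    ax.imshow(report.to_numpy(), aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(n_genes), report.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(n_genomes), report.index, fontsize=4)
    ax.set_xlabel("gene")
    ax.set_ylabel("genome (tree order)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
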