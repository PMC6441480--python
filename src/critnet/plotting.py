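"""Minimal diagnostic figures: per-sample box plots and the degree distribution."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .expression import ExpressionMatrix
from .topology import PowerLawFit

__all__ = ["save_expression_boxplot", "save_degree_distribution_plot"]


def save_expression_boxplot(matrix: ExpressionMatrix, path) -> None:
    """One box per sample of its log2 intensities, grouped by label."""
    fig, ax = plt.subplots(figsize=(1.2 * len(matrix.samples) + 2, 4))
    ax.boxplot(
        [matrix.values[s].to_numpy() for s in matrix.samples],
        tick_labels=[f"{s}\n({matrix.groups[s]})" for s in matrix.samples],
    )
    ax.set_ylabel("log2 intensity")
    ax.set_title("Per-sample expression distributions")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_degree_distribution_plot(
    dist, path, fit: PowerLawFit | None = None
) -> None:
    """Node count vs degree on log-log axes, optionally with the fitted power law."""
    ks = np.array([k for k, _ in dist], dtype=float)
    counts = np.array([c for _, c in dist], dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(ks, counts, "o", label="observed")
    if fit is not None:
        grid = np.geomspace(ks.min(), ks.max(), 100)
        ax.loglog(
            grid,
            fit.a * grid**fit.b,
            "-",
            label=f"fit: {fit.a:.3g} k^{fit.b:.3f} (R²={fit.r_squared:.3f})",
        )
    ax.set_xlabel("degree k")
    ax.set_ylabel("node count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
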