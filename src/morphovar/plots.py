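"""Figure helpers: configuration scatters, simulation histograms,
reconstructed mean outlines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .ordination import OrdinationResult
from .outline import Outline
from .simulation import PAIRS, SimulationResult


def plot_configuration(result: OrdinationResult, axes=(0, 1), path=None):
    """Scatter of group means (and specimens when available) on two axes."""
    i, j = axes
    fig, ax = plt.subplots(figsize=(5, 5))
    if result.specimen_scores is not None and result.specimen_scores.shape[1] > max(i, j):
        ax.scatter(
            result.specimen_scores[:, i],
            result.specimen_scores[:, j],
            s=6,
            color="0.7",
            zorder=1,
        )
    cfg = result.group_mean_config
    ax.scatter(cfg[:, i], cfg[:, j], s=40, zorder=2)
    for lab, (x, y) in zip(result.group_labels, cfg[:, [i, j]]):
        ax.annotate(lab, (x, y), fontsize=7, xytext=(2, 2), textcoords="offset points")
    pv = result.percent_variance
    ax.set_xlabel(f"{result.method} axis {i+1} ({pv[i]:.1f}%)")
    ax.set_ylabel(f"{result.method} axis {j+1} ({pv[j]:.1f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_simulation(result: SimulationResult, path=None):
    """Histograms of null Procrustes distances with the observed distance."""
    fig, axs = plt.subplots(1, len(PAIRS), figsize=(4 * len(PAIRS), 3.2))
    for ax, pair in zip(np.atleast_1d(axs), PAIRS):
        out = result.pairs[pair]
        ax.hist(out.simulated_d, bins=30, color="0.6")
        ax.axvline(out.observed_d, color="red")
        ax.set_title(f"{pair[0]} vs {pair[1]}", fontsize=9)
        ax.set_xlabel("Procrustes distance d")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_outlines(outlines: dict[str, Outline], path=None):
    """Overlay of (reconstructed) outlines, one per label."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for lab, outline in outlines.items():
        pts = np.vstack([outline.points, outline.points[0]])
        ax.plot(pts[:, 0], pts[:, 1], label=lab, lw=1)
    ax.set_aspect("equal")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
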