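"""Optional diagnostic plots for the measure battery (matplotlib, Agg)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import ECDF_HIGHLIGHTS, EvalMatrix, OrthoFit, RocCurve

__all__ = ["plot_ecdf", "plot_roc", "plot_regression", "plot_score_heatmap"]


def plot_ecdf(cdf_by_pipeline: dict, path) -> None:
    """Overlaid ECDFs of FDR-corrected F-test p-values."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, cdf in cdf_by_pipeline.items():
        ax.step(cdf["cutoff"], cdf["fraction"], where="post", label=name, lw=0.8)
    for c in ECDF_HIGHLIGHTS:
        ax.axvline(c, color="grey", ls="--", lw=0.6)
    ax.set_xlabel("FDR-corrected p-value cutoff")
    ax.set_ylabel("fraction of probes")
    if len(cdf_by_pipeline) <= 10:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(curves: dict[str, RocCurve], path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, c in curves.items():
        ax.plot(c.fpr, c.tpr, lw=0.9, label=f"{name} (AUC {c.auc:.3f})")
    ax.plot([0, 1], [0, 1], color="grey", ls="--", lw=0.6)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    if len(curves) <= 10:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_regression(x, y, fit: OrthoFit, path, title: str = "") -> None:
    """Reference vs pipeline log2 ratios with the orthogonal-regression line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=8, alpha=0.7)
    grid = np.linspace(min(x), max(x), 10)
    ax.plot(grid, fit.intercept + fit.slope * grid, color="red",
            label=f"y = {fit.slope:.3f}x + {fit.intercept:.3f}")
    ax.plot(grid, grid, color="grey", ls="--", lw=0.6)
    ax.set_xlabel("reference log2 ratio")
    ax.set_ylabel("pipeline log2 ratio")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_score_heatmap(ev: EvalMatrix, path) -> None:
    """Quality-score matrix in cluster order, row sums in the labels."""
    ordered = ev.scores.loc[ev.row_order, ev.col_order]
    fig, ax = plt.subplots(figsize=(1 + 0.5 * ordered.shape[1],
                                    1 + 0.25 * ordered.shape[0]))
    im = ax.imshow(ordered.to_numpy(), cmap="RdYlGn", vmin=-2, vmax=2,
                   aspect="auto")
    ax.set_xticks(range(ordered.shape[1]), ordered.columns,
                  rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(ordered.shape[0]),
                  [f"{p} ({ev.row_sums[p]})" for p in ordered.index], fontsize=7)
    fig.colorbar(im, ax=ax, label="quality score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
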