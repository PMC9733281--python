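"""Static PNG plots for the evaluation reports.

Content mirrors the standard quality-control views: MA scatter of one
array against the rest, per-array weight bars, and box plots of control
CVs per normalization method.  Styling is deliberately plain.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import MATable
from .quality import ArrayWeightResult


def plot_ma(ma: MATable, path) -> None:
    """MA scatter with the zero line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ma.table["A"], ma.table["M"], s=4, alpha=0.5)
    ax.axhline(0.0, color="grey", linewidth=0.8)
    ax.set_xlabel("A (mean log2 intensity)")
    ax.set_ylabel("M (log2 ratio vs rest)")
    ax.set_title(f"Array {ma.array} vs average of the rest")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_weights(weights: ArrayWeightResult, path) -> None:
    """Per-array weight bars with the unit line."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(range(len(weights.weights)), weights.weights.to_numpy())
    ax.axhline(1.0, color="grey", linewidth=0.8, linestyle="--")
    ax.set_xticks(range(len(weights.weights)))
    ax.set_xticklabels(weights.weights.index, rotation=45, ha="right")
    ax.set_ylabel("array weight")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cv_boxes(cv_tables: dict, path) -> None:
    """Box plots of control CVs per normalization method."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    labels = list(cv_tables)
    data = [cv_tables[m]["cv_pct"].dropna() for m in labels]
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("control CV (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
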