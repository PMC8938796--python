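"""Figure rendering for pipeline results (ROC curves, AUC boxes, selection
histograms)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_roc_curves", "plot_auc_boxes", "plot_selection_histogram", "render_all"]


def plot_roc_curves(reports: dict, path):
    fig, ax = plt.subplots(figsize=(5, 5))
    for group, rep in reports.items():
        fpr, tpr = rep.pooled_roc
        ax.plot(fpr, tpr, label=f"{group} (AUC={rep.pooled_auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="no skill")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_auc_boxes(reports: dict, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = list(reports)
    ax.boxplot([reports[g].per_repeat_auc for g in groups], tick_labels=groups)
    ax.set_ylabel("AUC per repeat")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_selection_histogram(report, path, top: int = 11):
    freq = report.selection_frequency.head(top)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.barh(range(len(freq))[::-1], freq.to_numpy())
    ax.set_yticks(range(len(freq))[::-1], freq.index, fontsize=6)
    ax.set_xlabel("selection count across CV folds")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_all(result, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plot_roc_curves(result.reports, out / "roc_curves.png")
    plot_auc_boxes(result.reports, out / "auc_boxplot.png")
    for g, rep in result.reports.items():
        plot_selection_histogram(rep, out / f"selection_{g}.png")
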