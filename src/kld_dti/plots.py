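"""Rendered diagnostics: ROC, confusion matrix, correlation map, pruning."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import EvaluationReport, FeatureAnalysis, LABEL_COLUMN, feature_columns


def plot_roc(report: EvaluationReport, path) -> None:
    """One-vs-rest ROC curve per target class with AUC in the legend."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for lbl, (fpr, tpr) in report.roc_curves.items():
        ax.plot(fpr, tpr, lw=1, label=f"{lbl} (AUC {report.auc[lbl]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.6)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_confusion(report: EvaluationReport, path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 5))
    conf = report.confusion.to_numpy()
    im = ax.imshow(conf, cmap="Blues")
    ax.set_xticks(range(len(report.labels)), report.labels, rotation=90)
    ax.set_yticks(range(len(report.labels)), report.labels)
    ax.set_xlabel("predicted target")
    ax.set_ylabel("true target")
    for i in range(conf.shape[0]):
        for j in range(conf.shape[1]):
            if conf[i, j]:
                ax.text(j, i, conf[i, j], ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlation(analysis: FeatureAnalysis, path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 5))
    corr = analysis.correlation
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pruning(analysis: FeatureAnalysis, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(analysis.pruning["n_features"], analysis.pruning["accuracy"],
            "o-", label="held-out accuracy")
    ax.plot(analysis.pruning["n_features"], analysis.pruning["oob_score"],
            "s--", label="out-of-bag score")
    ax.set_xlabel("number of retained KLD features")
    ax.set_ylabel("score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def percentile_rank_boxplot(model, table: pd.DataFrame, path) -> None:
    """Experimental: distribution of the percentile rank of each query's
    own-class KLD feature, grouped by whether the forest got the query
    right.  The construction of the published analog is under-specified,
    so treat this as a qualitative diagnostic only."""
    cols = feature_columns(table)
    X = table[cols].to_numpy()
    y = table[LABEL_COLUMN].to_numpy()
    correct = model.predict(X) == y
    ranks = []
    col_index = {c.split("_", 1)[1]: i for i, c in enumerate(cols)}
    for i, lbl in enumerate(y):
        if lbl not in col_index:
            continue
        own = X[i, col_index[lbl]]
        ranks.append(100.0 * (X[i] >= own).sum() / len(cols))
    ranks = np.asarray(ranks)
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = [ranks[correct[: len(ranks)]], ranks[~correct[: len(ranks)]]]
    ax.boxplot([g for g in groups if g.size], tick_labels=[
        n for n, g in zip(["correct", "incorrect"], groups) if g.size
    ])
    ax.set_ylabel("percentile rank of own-class KLD (smaller-is-better)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
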