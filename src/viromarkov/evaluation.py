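"""Classifier benchmarking: ROC/AUROC with bootstrap standard errors,
precision/recall versus the λ cutoff, and contaminant false-positive rates.

AUROC is computed from the Mann–Whitney U statistic with midrank tie
handling, i.e. the probability that a randomly chosen positive outscores a
randomly chosen negative (ties counting one half), which equals the area
under the threshold-sweep ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RocResult",
    "auroc",
    "bootstrap_se",
    "precision_recall_vs_lambda",
    "PrecisionRecallResult",
    "contaminant_fpr",
    "hanley_mcneil_se",
    "plot_roc",
]


@dataclass
class RocResult:
    auc: float
    curve: np.ndarray  # (n_points, 2) of (FPR, TPR), from (0,0) to (1,1)
    n_pos: int
    n_neg: int
    bootstrap_se: float | None = None
    n_bootstrap: int = 0


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0 (negative) or 1 (positive)")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("both classes must be present to compute a ROC curve")
    return scores, labels


def _auc_mw(scores: np.ndarray, labels: np.ndarray) -> float:
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # midranks: ties credit 0.5
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """AUROC plus the full (FPR, TPR) curve from a threshold sweep."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(-scores, kind="mergesort")
    ls = labels[order]
    ss = scores[order]
    tps = np.cumsum(ls)
    fps = np.cumsum(1 - ls)
    last_of_block = np.r_[np.nonzero(np.diff(ss))[0], ss.size - 1]
    tpr = np.r_[0.0, tps[last_of_block] / n_pos]
    fpr = np.r_[0.0, fps[last_of_block] / n_neg]
    return RocResult(
        auc=_auc_mw(scores, labels),
        curve=np.column_stack([fpr, tpr]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def bootstrap_se(
    scores: Sequence[float],
    labels: Sequence[int],
    n_bootstrap: int = 30,
    seed: int | None = None,
) -> float:
    """Sample standard deviation of AUROC over bootstrap resamples.

    Resampling is with replacement, stratified by class, so AUROC is defined
    in every replicate.
    """
    scores, labels = _validate(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    aucs = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        take = np.r_[rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        aucs[b] = _auc_mw(scores[take], labels[take])
    return float(aucs.std(ddof=1))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form approximation to the standard error of an AUC."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class PrecisionRecallResult:
    table: "object"  # pandas DataFrame: cutoff, tp, fp, fn, precision, recall, f1
    crossover_cutoff: float | None


def precision_recall_vs_lambda(
    scores: Sequence[float], labels: Sequence[int], cutoffs: Sequence[float]
) -> PrecisionRecallResult:
    """Precision/recall/F1 of the call "λ >= cutoff is viral" at each cutoff.

    Precision is NA when no call is made.  Also reports the cutoff where
    |precision − recall| is smallest (where the two curves cross).
    """
    import pandas as pd

    scores, labels = _validate(scores, labels)
    rows = []
    for c in cutoffs:
        called = scores >= c
        tp = int((called & (labels == 1)).sum())
        fp = int((called & (labels == 0)).sum())
        fn = int((~called & (labels == 1)).sum())
        precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        recall = tp / (tp + fn)
        f1 = (
            2 * precision * recall / (precision + recall)
            if (tp + fp) > 0 and (precision + recall) > 0
            else np.nan
        )
        rows.append((float(c), tp, fp, fn, precision, recall, f1))
    table = pd.DataFrame(rows, columns=["cutoff", "tp", "fp", "fn", "precision", "recall", "f1"])
    defined = table.dropna(subset=["precision"])
    crossover = None
    if not defined.empty:
        gap = (defined["precision"] - defined["recall"]).abs()
        crossover = float(defined.loc[gap.idxmin(), "cutoff"])
    return PrecisionRecallResult(table=table, crossover_cutoff=crossover)


def contaminant_fpr(scores: Sequence[float], cutoff: float) -> float:
    """Fraction of contaminant-only fragments called viral (λ >= cutoff)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    return float((scores >= cutoff).mean())


def plot_roc(result: RocResult, ax=None, label: str | None = None):
    """Plot a ROC curve; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    lab = label or f"AUC = {result.auc:.3f}"
    ax.plot(result.curve[:, 0], result.curve[:, 1], label=lab)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    return ax
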