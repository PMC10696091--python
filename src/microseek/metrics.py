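"""One-vs-all classifier metrics: AUROC, AUPRC, and the curves behind them.

Both areas use half-credit tie handling: AUROC is the Mann-Whitney U
statistic (tied pairs count 1/2) normalized by n_pos * n_neg, and AUPRC is
average precision computed over tie groups, so items with identical scores
enter the curve as one block.  Both reduce to the familiar step-curve areas
when scores are distinct, and both are checkable against brute-force pair
enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .simulate import ORIGIN_LABELS


def auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Rank-based AUROC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(positives, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks implement the half-credit rule
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_curve(scores: np.ndarray, positives: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Precision/recall at each distinct descending score threshold (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(positives, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    # group boundaries: last index of each tie block
    boundary = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(boundary, len(s) - 1)
    tp = np.cumsum(p)[ends]
    n_at = ends + 1
    precision = tp / n_at
    recall = tp / max(int(pos.sum()), 1)
    return precision, recall


def auprc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Average precision over tie groups: sum of delta-recall * precision."""
    pos = np.asarray(positives, dtype=bool)
    if int(pos.sum()) == 0:
        raise ValueError("AUPRC needs at least one positive")
    precision, recall = pr_curve(scores, positives)
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(d_recall * precision))


def roc_curve(scores: np.ndarray, positives: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FPR/TPR at each distinct descending threshold (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(positives, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    boundary = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(boundary, len(s) - 1)
    tp = np.cumsum(p)[ends]
    fp = (ends + 1) - tp
    tpr = np.concatenate([[0.0], tp / max(int(pos.sum()), 1)])
    fpr = np.concatenate([[0.0], fp / max(int((~pos).sum()), 1)])
    return fpr, tpr


def evaluate_scores(
    probs: np.ndarray, labels: np.ndarray, class_names: tuple[str, ...] = ORIGIN_LABELS
) -> dict[str, dict[str, float] | None]:
    """Per-class one-vs-all AUPRC and AUROC from an (n, k) probability matrix.

    A class absent from the labels gets ``None`` (metrics undefined).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, dict[str, float] | None] = {}
    for k, name in enumerate(class_names):
        positives = labels == k
        if positives.sum() == 0:
            out[name] = None
            continue
        out[name] = {
            "auprc": auprc(probs[:, k], positives),
            "auroc": auroc(probs[:, k], positives),
        }
    return out


def mean_metric(per_class: dict[str, dict[str, float] | None], key: str) -> float:
    vals = [m[key] for m in per_class.values() if m is not None]
    return float(np.mean(vals))
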