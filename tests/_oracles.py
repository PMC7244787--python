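"""Independent brute-force oracles used across the test suite.

Deliberately naive: pair counting for AUROC, an explicit threshold sweep
for AUPRC, and exhaustive k-NN plus segment membership for SMOTE.  None of
them shares code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_auroc(scores, labels) -> float:
    """Mann-Whitney by explicit enumeration of all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_auprc(scores, labels) -> float:
    """Average precision as an explicit descending-threshold sweep.

    Equal scores are one tie group: precision/recall are only evaluated
    after a whole group is admitted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    area = 0.0
    prev_recall = 0.0
    tp = fp = 0
    for threshold in sorted(set(scores), reverse=True):
        group = labels[scores == threshold]
        tp += int((group == 1).sum())
        fp += int((group == 0).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def brute_knn(points: np.ndarray, i: int, k: int) -> list[int]:
    """Indices of the k nearest neighbours of row i (Euclidean, self excluded)."""
    dists = np.linalg.norm(points - points[i], axis=1)
    order = [j for j in np.argsort(dists, kind="stable") if j != i]
    return order[: min(k, len(points) - 1)]


def on_segment(s: np.ndarray, p: np.ndarray, q: np.ndarray, tol: float = 1e-9) -> bool:
    """True when s = p + u (q - p) for some u in [0, 1] within tolerance."""
    d = q - p
    denom = float(d @ d)
    if denom == 0.0:
        return bool(np.linalg.norm(s - p) <= tol)
    u = float((s - p) @ d) / denom
    if u < -tol or u > 1 + tol:
        return False
    residual = np.linalg.norm(s - (p + u * d))
    return residual <= tol


def smote_row_valid(s: np.ndarray, positives: np.ndarray, source: int, k: int) -> bool:
    """Check one synthetic row against its source positive's k-NN segments."""
    p = positives[source]
    return any(on_segment(s, p, positives[j]) for j in brute_knn(positives, source, k))
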