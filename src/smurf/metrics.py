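"""Ranking metrics: AUROC and AUPRC.

AUROC equals the Mann-Whitney statistic P(score_pos > score_neg) + half the
tie probability over all positive-negative pairs.  AUPRC is the
non-interpolated average-precision step sum, with equal scores processed as
a single tie group (linear PR interpolation is known to be optimistic and is
not used).  Under the extreme class imbalance this package targets, AUPRC is
the informative metric and is the tuning objective; AUROC saturates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve

from .exceptions import MetricUndefinedError


def _check(scores: np.ndarray, labels: np.ndarray, need_both: bool) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 1 or labels.ndim != 1 or len(scores) != len(labels) or len(scores) == 0:
        raise MetricUndefinedError("scores and labels must be equal-length non-empty vectors")
    if not np.isin(labels, (0, 1)).all():
        raise MetricUndefinedError("labels must contain only {0, 1}")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0:
        raise MetricUndefinedError("metric undefined: no positive labels")
    if need_both and n_neg == 0:
        raise MetricUndefinedError("metric undefined: no negative labels")
    return scores, labels.astype(int)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (both classes required)."""
    scores, labels = _check(scores, labels, need_both=True)
    return float(roc_auc_score(labels, scores))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve, average-precision form."""
    scores, labels = _check(scores, labels, need_both=False)
    return float(average_precision_score(labels, scores))


def roc_curve_table(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC operating points as a (threshold, fpr, tpr) table."""
    scores, labels = _check(scores, labels, need_both=True)
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def pr_curve_table(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Precision-recall operating points as a (threshold, recall, precision) table."""
    scores, labels = _check(scores, labels, need_both=False)
    precision, recall, thr = precision_recall_curve(labels, scores)
    # precision_recall_curve appends the (recall=0, precision=1) endpoint
    thr = np.append(thr, np.nan)
    return pd.DataFrame({"threshold": thr, "recall": recall, "precision": precision})


def dump_curves(scores: np.ndarray, labels: np.ndarray, directory: str | Path, prefix: str = "curve") -> None:
    """Write ROC and PR operating-point tables as TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    roc_curve_table(scores, labels).to_csv(directory / f"{prefix}_roc.tsv", sep="\t", index=False)
    pr_curve_table(scores, labels).to_csv(directory / f"{prefix}_pr.tsv", sep="\t", index=False)
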