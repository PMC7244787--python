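"""Cross-validation fold construction.

Three schemes:

* plain stratified k-fold (per-class counts even to within one);
* cytogenetic-band-aware k-fold — whole bands are assigned to folds so
  variants of the same band never straddle the train/test boundary; bands
  are placed by a deterministic longest-processing-time greedy rule that
  balances fold positive counts;
* the "per region balanced" subsample, which equalises the negative:positive
  imbalance across regulatory-region categories by downsampling negatives to
  the smallest per-category imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError


@dataclass
class FoldAssignment:
    """Per-sample fold indices in ``[0, n_folds)``."""

    fold_of: np.ndarray
    n_folds: int

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of, dtype=int)
        if self.fold_of.min(initial=0) < 0 or (
            self.fold_of.size and self.fold_of.max() >= self.n_folds
        ):
            raise ConfigurationError("fold indices must lie in [0, n_folds)")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def stratified_kfold(labels: np.ndarray, n_folds: int, seed: int) -> FoldAssignment:
    """Stratified folds: positives and negatives each split evenly (±1)."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ConfigurationError(f"n_folds must be >= 2, got {n_folds}")
    if n_folds > len(labels):
        raise ConfigurationError(
            f"n_folds={n_folds} exceeds the number of samples ({len(labels)})"
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((len(labels), 1)), labels)):
        fold_of[test_idx] = fold
    return FoldAssignment(fold_of=fold_of, n_folds=n_folds)


def band_aware_kfold(
    band_ids: np.ndarray, labels: np.ndarray, n_folds: int, seed: int = 0
) -> FoldAssignment:
    """Assign whole bands to folds, balancing fold positive counts.

    Bands are sorted by descending positive count (ties: descending total
    size, then band id) and each is placed in the fold currently lightest in
    positives (ties: smallest total size, then lowest fold index) — the
    longest-processing-time greedy heuristic.  ``seed`` is accepted for
    interface symmetry; the rule itself is deterministic.
    """
    band_ids = np.asarray(band_ids)
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ConfigurationError(f"n_folds must be >= 2, got {n_folds}")
    if len(band_ids) != len(labels):
        raise ConfigurationError("band_ids and labels must have equal length")
    bands, inverse = np.unique(band_ids, return_inverse=True)
    if len(bands) < n_folds:
        raise ConfigurationError(
            f"band-aware CV needs at least n_folds={n_folds} distinct bands, found {len(bands)}"
        )
    pos_per_band = np.bincount(inverse, weights=(labels == 1)).astype(int)
    size_per_band = np.bincount(inverse).astype(int)
    order = sorted(
        range(len(bands)),
        key=lambda b: (-pos_per_band[b], -size_per_band[b], str(bands[b])),
    )
    fold_pos = np.zeros(n_folds, dtype=int)
    fold_size = np.zeros(n_folds, dtype=int)
    band_fold = np.empty(len(bands), dtype=int)
    for b in order:
        target = min(range(n_folds), key=lambda f: (fold_pos[f], fold_size[f], f))
        band_fold[b] = target
        fold_pos[target] += pos_per_band[b]
        fold_size[target] += size_per_band[b]
    return FoldAssignment(fold_of=band_fold[inverse], n_folds=n_folds)


def region_balanced_subsample(
    labels: np.ndarray, category_ids: np.ndarray, seed: int
) -> np.ndarray:
    """Mark a subset with equal negative:positive imbalance in every category.

    The target imbalance ``r*`` is the minimum over categories of
    ``negatives_c / positives_c``.  Each category keeps all its positives and
    a uniform sample of ``floor(r* * positives_c)`` negatives; the returned
    boolean vector marks membership.
    """
    labels = np.asarray(labels)
    category_ids = np.asarray(category_ids)
    if len(labels) != len(category_ids):
        raise ConfigurationError("labels and category_ids must have equal length")
    categories = np.unique(category_ids)
    ratios = {}
    for c in categories:
        mask = category_ids == c
        n_pos = int((labels[mask] == 1).sum())
        n_neg = int((labels[mask] == 0).sum())
        if n_pos == 0:
            raise ConfigurationError(f"category {c!r} contains no positive samples")
        if n_neg == 0:
            raise ConfigurationError(f"category {c!r} contains no negative samples")
        ratios[c] = n_neg / n_pos
    r_star = min(ratios.values())
    rng = np.random.default_rng(seed)
    marked = np.zeros(len(labels), dtype=bool)
    for c in categories:
        mask = category_ids == c
        marked[mask & (labels == 1)] = True
        neg_idx = np.flatnonzero(mask & (labels == 0))
        n_pos = int((labels[mask] == 1).sum())
        keep = int(np.floor(r_star * n_pos))
        keep = min(keep, len(neg_idx))
        marked[rng.choice(neg_idx, size=keep, replace=False)] = True
    return marked


def write_folds(assignment: FoldAssignment, path: str | Path) -> None:
    """One integer fold index per line, aligned with the sample rows."""
    Path(path).write_text("".join(f"{f}\n" for f in assignment.fold_of))


def read_folds(path: str | Path) -> FoldAssignment:
    fold_of = np.array([int(line) for line in Path(path).read_text().split()])
    return FoldAssignment(fold_of=fold_of, n_folds=int(fold_of.max()) + 1)
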