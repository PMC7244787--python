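"""Run modes: repeated (band-aware) external CV and nested tuning.

``run_cv`` estimates generalisation by external k-fold CV, optionally
repeated with re-drawn folds; every sample is scored exactly once per
repeat.  ``run_nested_tune`` selects hyper-parameters per external fold by
an internal search restricted to that fold's training portion, so no test
sample ever influences tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import hyper_ensemble
from .datamodel import Dataset, HyperParams
from .exceptions import ConfigurationError
from .folds import FoldAssignment, band_aware_kfold, stratified_kfold
from .metrics import auprc, auroc
from .tuning import ParamSpace, TuneResult, bayes_search, grid_search


@dataclass
class CVReport:
    """Out-of-fold scores and per-fold metrics of a repeated external CV."""

    scores: np.ndarray  # (n_repeats, n_samples) out-of-fold scores
    fold_metrics: pd.DataFrame  # columns: repeat, fold, auroc, auprc
    n_folds: int
    n_repeats: int

    @property
    def mean_auprc(self) -> float:
        return float(self.fold_metrics["auprc"].mean())

    @property
    def mean_auroc(self) -> float:
        return float(self.fold_metrics["auroc"].mean())

    def summary(self) -> dict:
        g = self.fold_metrics
        return {
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "auroc_mean": float(g["auroc"].mean()),
            "auroc_sd": float(g["auroc"].std(ddof=1)) if len(g) > 1 else 0.0,
            "auprc_mean": float(g["auprc"].mean()),
            "auprc_sd": float(g["auprc"].std(ddof=1)) if len(g) > 1 else 0.0,
        }


def _external_folds(dataset: Dataset, n_folds: int, seed: int, band_aware: bool) -> FoldAssignment:
    if band_aware:
        if dataset.band_ids is None:
            raise ConfigurationError("band-aware CV requested but the dataset has no band ids")
        return band_aware_kfold(dataset.band_ids, dataset.labels, n_folds, seed)
    return stratified_kfold(dataset.labels, n_folds, seed)


def run_cv(
    dataset: Dataset,
    h: HyperParams,
    n_folds: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    n_workers: int = 1,
    band_aware: bool = False,
) -> CVReport:
    """Repeated external CV; folds are re-drawn per repeat via a seed offset."""
    all_scores = np.empty((n_repeats, dataset.n_samples))
    rows = []
    for repeat in range(n_repeats):
        repeat_seed = seed + repeat
        assignment = _external_folds(dataset, n_folds, repeat_seed, band_aware)
        for fold in range(n_folds):
            train_idx = assignment.train_indices(fold)
            test_idx = assignment.test_indices(fold)
            model = hyper_ensemble.train(
                dataset.subset(train_idx), h, n_workers=n_workers, master_seed=repeat_seed + 1000 * fold
            )
            scores = hyper_ensemble.predict(model, dataset.features[test_idx])
            all_scores[repeat, test_idx] = scores
            rows.append(
                {
                    "repeat": repeat,
                    "fold": fold,
                    "auroc": auroc(scores, dataset.labels[test_idx]),
                    "auprc": auprc(scores, dataset.labels[test_idx]),
                }
            )
    return CVReport(
        scores=all_scores,
        fold_metrics=pd.DataFrame(rows),
        n_folds=n_folds,
        n_repeats=n_repeats,
    )


@dataclass
class NestedTuneReport:
    """Per-external-fold selected hyper-parameters and test metrics."""

    best_params: list[HyperParams]
    tune_results: list[TuneResult]
    fold_metrics: pd.DataFrame
    scores: np.ndarray
    n_folds: int

    @property
    def mean_auprc(self) -> float:
        return float(self.fold_metrics["auprc"].mean())


def run_nested_tune(
    dataset: Dataset,
    space: ParamSpace,
    n_folds_external: int = 10,
    n_folds_internal: int = 9,
    strategy: str = "grid",
    seed: int = 0,
    n_workers: int = 1,
    band_aware: bool = False,
    max_iter: int = 60,
    n_init: int = 10,
) -> NestedTuneReport:
    """Nested CV: tune per external fold, then score that fold's test set."""
    if strategy not in ("grid", "bayes"):
        raise ConfigurationError(f"unknown tuning strategy {strategy!r}")
    assignment = _external_folds(dataset, n_folds_external, seed, band_aware)
    best_params: list[HyperParams] = []
    tune_results: list[TuneResult] = []
    rows = []
    scores = np.empty(dataset.n_samples)
    for fold in range(n_folds_external):
        train_idx = assignment.train_indices(fold)
        test_idx = assignment.test_indices(fold)
        train_split = dataset.subset(train_idx)
        if strategy == "grid":
            result = grid_search(space, train_split, n_folds_internal, seed + fold, n_workers)
        else:
            result = bayes_search(
                space,
                train_data=train_split,
                n_folds=n_folds_internal,
                max_iter=max_iter,
                n_init=n_init,
                seed=seed + fold,
                n_workers=n_workers,
            )
        tune_results.append(result)
        best_params.append(result.best)
        model = hyper_ensemble.train(
            train_split, result.best, n_workers=n_workers, master_seed=seed + 1000 * fold
        )
        fold_scores = hyper_ensemble.predict(model, dataset.features[test_idx])
        scores[test_idx] = fold_scores
        rows.append(
            {
                "fold": fold,
                "auroc": auroc(fold_scores, dataset.labels[test_idx]),
                "auprc": auprc(fold_scores, dataset.labels[test_idx]),
                **{f"best_{k}": v for k, v in result.best.as_dict().items()},
            }
        )
    return NestedTuneReport(
        best_params=best_params,
        tune_results=tune_results,
        fold_metrics=pd.DataFrame(rows),
        scores=scores,
        n_folds=n_folds_external,
    )
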