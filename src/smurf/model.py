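"""Model/Results interface over the hyper-ensemble.

``SmurfModel`` holds the data and hyper-parameters; ``fit`` trains the
hyper-ensemble and returns a ``SmurfResults`` carrying the fitted forests,
per-part training metadata, and evaluation helpers.  This mirrors the
fit-then-results idiom of statistical modelling packages while the
functional API (``smurf.train`` / ``smurf.predict``) stays available.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import hyper_ensemble
from .datamodel import Dataset, HyperParams
from .metrics import auprc, auroc


class SmurfModel:
    """A hyper-ensemble model bound to a training dataset.

    Parameters
    ----------
    features, labels : arrays
        Training matrix (n_samples x n_features) and binary labels
        (1 = minority/positive).
    band_ids, category_ids : arrays, optional
        Locality-group / region-category annotations used by the
        cross-validation helpers.
    params : HyperParams, optional
        Learning hyper-parameters; defaults to
        (n_parts=100, fp=2, ratio=3, k=5, n_trees=10, m_try=5).
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        band_ids: Optional[np.ndarray] = None,
        category_ids: Optional[np.ndarray] = None,
        params: Optional[HyperParams] = None,
    ) -> None:
        self.data = Dataset(
            features=features, labels=labels, band_ids=band_ids, category_ids=category_ids
        )
        self.params = params if params is not None else HyperParams()

    @classmethod
    def from_dataset(cls, dataset: Dataset, params: Optional[HyperParams] = None) -> "SmurfModel":
        model = cls.__new__(cls)
        model.data = dataset
        model.params = params if params is not None else HyperParams()
        return model

    def fit(self, seed: int = 0, n_workers: int = 1) -> "SmurfResults":
        ensemble = hyper_ensemble.train(
            self.data, self.params, n_workers=n_workers, master_seed=seed
        )
        return SmurfResults(self, ensemble)


class SmurfResults:
    """Results of a fitted hyper-ensemble."""

    def __init__(self, model: SmurfModel, ensemble: hyper_ensemble.EnsembleModel) -> None:
        self.model = model
        self.ensemble = ensemble

    @property
    def params(self) -> HyperParams:
        return self.ensemble.h

    def predict(self, X: np.ndarray, n_workers: int = 1) -> np.ndarray:
        """Consensus positive-class score in [0, 1] for each row of ``X``."""
        return hyper_ensemble.predict(self.ensemble, X, n_workers=n_workers)

    def evaluate(self, X: np.ndarray, labels: np.ndarray) -> dict[str, float]:
        """AUROC and AUPRC of the consensus score on labelled data."""
        scores = self.predict(X)
        return {"auroc": auroc(scores, labels), "auprc": auprc(scores, labels)}

    def training_table(self) -> pd.DataFrame:
        """Per-part training-set composition."""
        return pd.DataFrame(self.ensemble.training_meta)

    def save(self, path) -> None:
        hyper_ensemble.save_model(self.ensemble, path)

    def summary(self) -> str:
        h = self.ensemble.h
        meta = self.training_table()
        lines = [
            "Hyper-ensemble of SMOTE-oversampled, undersampled random forests",
            "=" * 64,
            f"forests (n_parts):        {h.n_parts}",
            f"trees per forest:         {h.n_trees}",
            f"features per split:       {h.m_try}",
            f"SMOTE factor fp:          {h.fp} (k={h.k} neighbours)",
            f"undersampling ratio:      {h.ratio}",
            f"master seed:              {self.ensemble.master_seed}",
            f"n_features:               {self.ensemble.n_features}",
            "-" * 64,
            f"positives per part:       {int(meta['n_original_positives'].iloc[0])} original "
            f"+ {int(meta['n_synthetic_positives'].iloc[0])} synthetic",
            f"negatives per part:       min={int(meta['n_sampled_negatives'].min())} "
            f"max={int(meta['n_sampled_negatives'].max())}",
            "=" * 64,
        ]
        return "\n".join(lines)
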