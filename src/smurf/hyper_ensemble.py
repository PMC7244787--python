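"""Training and prediction of the random-forest hyper-ensemble.

One forest is trained per part of the negative partition; parts are grouped
into chunks, one chunk per worker.  Per-part RNG streams are derived from
``(master_seed, part_index)`` alone, so the trained model — and therefore
every downstream score — is bit-identical for any worker count.  Prediction
averages the per-forest positive-class probabilities, each forest's
probability being the mean over its trees of the tree-level class-proportion
estimate (the standard probability-forest rule).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestClassifier

from .datamodel import Dataset, HyperParams
from .exceptions import ConfigurationError, DataFormatError, ModelIOError
from .sampling import assemble_part, partition_negatives, smote_neighbor_table

MODEL_FORMAT_VERSION = "smurf-model-1"


@dataclass
class ChunkPlan:
    """Assignment of partition parts to parallel workers."""

    chunks: list[list[int]]

    @property
    def q(self) -> int:
        return len(self.chunks)


@dataclass
class EnsembleModel:
    """A trained hyper-ensemble: ``n_parts`` fitted forests plus provenance."""

    forests: list[RandomForestClassifier]
    h: HyperParams
    master_seed: int
    n_features: int
    training_meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.forests) != self.h.n_parts:
            raise ConfigurationError(
                f"model holds {len(self.forests)} forests but n_parts={self.h.n_parts}"
            )


def plan_chunks(n_parts: int, q: int) -> ChunkPlan:
    """Split part indices [0, n_parts) into ``q`` blocks of near-equal size.

    Sizes differ by at most one; when ``q > n_parts`` the trailing chunks
    are empty.
    """
    if q < 1:
        raise ConfigurationError(f"worker count q must be >= 1, got {q}")
    if n_parts < 1:
        raise ConfigurationError(f"n_parts must be >= 1, got {n_parts}")
    return ChunkPlan(chunks=[list(c) for c in np.array_split(np.arange(n_parts), q)])


def _fit_part(
    dataset: Dataset,
    part_negatives: np.ndarray,
    h: HyperParams,
    master_seed: int,
    part_index: int,
    neighbor_index: np.ndarray | None,
) -> tuple[RandomForestClassifier, dict]:
    training_set = assemble_part(
        dataset, part_negatives, h, master_seed, part_index, neighbor_index=neighbor_index
    )
    # forest seeded from the same per-part derivation used for sampling
    forest_seed = int(
        np.random.SeedSequence(master_seed, spawn_key=(part_index,)).generate_state(1)[0]
        % (2**31 - 1)
    )
    forest = RandomForestClassifier(
        n_estimators=h.n_trees,
        max_features=h.m_try,
        random_state=forest_seed,
        n_jobs=1,
    )
    forest.fit(training_set.X, training_set.y)
    meta = {
        "part_index": part_index,
        "n_original_positives": int((training_set.provenance == "original_positive").sum()),
        "n_synthetic_positives": int((training_set.provenance == "synthetic_positive").sum()),
        "n_sampled_negatives": training_set.n_negatives,
    }
    return forest, meta


def train(
    dataset: Dataset,
    h: HyperParams,
    n_workers: int = 1,
    master_seed: int = 0,
) -> EnsembleModel:
    """Train the hyper-ensemble.

    The negatives are partitioned with ``master_seed``; part *i* is assembled
    and its forest fitted under an RNG stream derived from
    ``(master_seed, i)``.  The returned model is identical for every
    ``n_workers >= 1``.

    Raises
    ------
    ConfigurationError
        Before any training starts, if the dataset has no positives, fewer
        negatives than ``n_parts``, or ``m_try`` exceeds the feature count.
    """
    if dataset.n_positives < 1:
        raise ConfigurationError("training requires at least one positive sample")
    if dataset.n_negatives < h.n_parts:
        raise ConfigurationError(
            f"n_parts={h.n_parts} exceeds the number of negatives ({dataset.n_negatives})"
        )
    h.validate_for(dataset.n_features)
    if h.fp > 0 and dataset.n_positives < 2:
        raise ConfigurationError("SMOTE requires >=2 positives when fp > 0")

    parts = partition_negatives(dataset, h.n_parts, master_seed)
    neighbor_index = None
    if h.fp > 0:
        # every part shares the full positive set; compute the k-NN table once
        neighbor_index = smote_neighbor_table(dataset.features[dataset.positive_indices], h.k)

    plan = plan_chunks(h.n_parts, n_workers)

    def _fit_chunk(chunk: list[int]) -> list[tuple[int, RandomForestClassifier, dict]]:
        out = []
        for i in chunk:
            forest, meta = _fit_part(dataset, parts[i], h, master_seed, i, neighbor_index)
            out.append((i, forest, meta))
        return out

    if n_workers == 1:
        chunk_results = [_fit_chunk(c) for c in plan.chunks]
    else:
        chunk_results = Parallel(n_jobs=n_workers, backend="threading")(
            delayed(_fit_chunk)(c) for c in plan.chunks
        )
    fitted: list[RandomForestClassifier | None] = [None] * h.n_parts
    metas: list[dict | None] = [None] * h.n_parts
    for chunk in chunk_results:
        for i, forest, meta in chunk:
            fitted[i] = forest
            metas[i] = meta
    return EnsembleModel(
        forests=fitted,  # type: ignore[arg-type]
        h=h,
        master_seed=master_seed,
        n_features=dataset.n_features,
        training_meta=metas,  # type: ignore[arg-type]
    )


def _forest_positive_proba(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    proba = forest.predict_proba(X)
    classes = list(forest.classes_)
    if 1 not in classes:
        return np.zeros(X.shape[0])
    return proba[:, classes.index(1)]


def predict(model: EnsembleModel, X: np.ndarray, n_workers: int = 1) -> np.ndarray:
    """Consensus score: mean positive-class probability across the forests."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise DataFormatError(
            f"test matrix has {X.shape[1] if X.ndim == 2 else 'invalid'} features, "
            f"model expects {model.n_features}"
        )
    if n_workers == 1:
        per_part = [_forest_positive_proba(f, X) for f in model.forests]
    else:
        per_part = Parallel(n_jobs=n_workers, backend="threading")(
            delayed(_forest_positive_proba)(f, X) for f in model.forests
        )
    return np.mean(per_part, axis=0)


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Serialise the ensemble to a single archive with a format-version tag."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "h": model.h.as_dict(),
        "master_seed": model.master_seed,
        "n_features": model.n_features,
        "training_meta": model.training_meta,
        "forests": model.forests,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> EnsembleModel:
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file {path} does not exist")
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError) as exc:
        raise ModelIOError(f"model file {path} is corrupt: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"model file {path} has unsupported format "
            f"{payload.get('format_version') if isinstance(payload, dict) else '?'!r}"
        )
    return EnsembleModel(
        forests=payload["forests"],
        h=HyperParams(**payload["h"]),
        master_seed=payload["master_seed"],
        n_features=payload["n_features"],
        training_meta=payload["training_meta"],
    )
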