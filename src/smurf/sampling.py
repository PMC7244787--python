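"""Partitioning, SMOTE oversampling, undersampling, and training-set assembly.

Each part of the negative partition is joined with *all* original positives,
``fp`` SMOTE-synthesised positives per original positive, and a uniform
sample of ``ratio * (1 + fp) * n_pos`` of the part's negatives, producing a
balanced training set for one forest of the hyper-ensemble.

SMOTE synthesises a positive as ``p + u * (q - p)`` with ``u ~ U[0, 1)`` and
``q`` drawn uniformly among the ``k`` nearest positive neighbours of ``p``
(Euclidean distance, ``p`` itself excluded).  Neighbours are resampled
independently for each synthetic row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .datamodel import Dataset, HyperParams
from .exceptions import ConfigurationError

PROV_ORIGINAL_POSITIVE = "original_positive"
PROV_SYNTHETIC_POSITIVE = "synthetic_positive"
PROV_SAMPLED_NEGATIVE = "sampled_negative"


@dataclass
class PartTrainingSet:
    """The assembled, balanced training set of one partition part."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # one of the PROV_* strings per row
    part_index: int

    @property
    def n_positives(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_negatives(self) -> int:
        return int((self.y == 0).sum())


def part_seed(master_seed: int, part_index: int) -> np.random.Generator:
    """Deterministic per-part RNG, independent of worker scheduling.

    Uses a ``SeedSequence`` keyed on (master_seed, part_index) so the stream
    for part *i* never depends on how parts are grouped into chunks.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(part_index,)))


def partition_negatives(dataset: Dataset, n_parts: int, seed: int) -> list[np.ndarray]:
    """Split the negative sample indices into ``n_parts`` disjoint sets.

    The sets cover all negatives, their sizes differ by at most one, and the
    assignment is a uniformly random shuffle determined by ``seed``.
    """
    if n_parts < 1:
        raise ConfigurationError(f"n_parts must be >= 1, got {n_parts}")
    negatives = dataset.negative_indices
    if n_parts > len(negatives):
        raise ConfigurationError(
            f"n_parts={n_parts} exceeds the number of negatives ({len(negatives)})"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(negatives)
    return [np.sort(chunk) for chunk in np.array_split(shuffled, n_parts)]


def smote_oversample(
    positives: np.ndarray,
    fp: int,
    k: int,
    rng: np.random.Generator,
    neighbor_index: np.ndarray | None = None,
) -> np.ndarray:
    """Synthesise ``fp`` new rows per original positive by SMOTE interpolation.

    Parameters
    ----------
    positives : (n_pos, d) array
        The original positive rows.
    fp : int
        Synthetic rows per original positive; 0 returns an empty matrix.
    k : int
        Nearest-neighbour count; clamped to ``n_pos - 1`` when larger.
    rng : numpy Generator
        Source of the interpolation weights and neighbour choices.
    neighbor_index : (n_pos, k_eff) int array, optional
        Precomputed k-NN table (row i lists the neighbours of positive i,
        self excluded).  Positives are identical in every part, so the
        table is computed once per training run and reused.
    """
    positives = np.asarray(positives, dtype=float)
    n_pos, d = positives.shape
    if fp == 0:
        return np.empty((0, d), dtype=float)
    if n_pos < 2:
        raise ConfigurationError("SMOTE requires >=2 positives when fp > 0")
    if neighbor_index is None:
        neighbor_index = smote_neighbor_table(positives, k)
    k_eff = neighbor_index.shape[1]
    synthetic = np.empty((fp * n_pos, d), dtype=float)
    row = 0
    for i in range(n_pos):
        p = positives[i]
        for _ in range(fp):
            q = positives[neighbor_index[i, rng.integers(k_eff)]]
            u = rng.random()
            synthetic[row] = p + u * (q - p)
            row += 1
    return synthetic


def smote_neighbor_table(positives: np.ndarray, k: int) -> np.ndarray:
    """k-NN table over the positives (Euclidean, self excluded, k clamped)."""
    n_pos = positives.shape[0]
    k_eff = min(k, n_pos - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(positives)
    _, idx = nn.kneighbors(positives)
    # drop the self column; NearestNeighbors returns self first for exact data
    table = np.empty((n_pos, k_eff), dtype=int)
    for i in range(n_pos):
        row = idx[i][idx[i] != i]
        table[i] = row[:k_eff]
    return table


def undersample_negatives(
    negative_indices: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample without replacement of size ``min(target, available)``."""
    if target < 0:
        raise ConfigurationError(f"undersampling target must be >= 0, got {target}")
    negative_indices = np.asarray(negative_indices)
    size = min(int(target), len(negative_indices))
    if size == 0:
        return np.empty(0, dtype=negative_indices.dtype)
    return rng.choice(negative_indices, size=size, replace=False)


def assemble_part(
    dataset: Dataset,
    part_negatives: np.ndarray,
    h: HyperParams,
    master_seed: int,
    part_index: int,
    neighbor_index: np.ndarray | None = None,
) -> PartTrainingSet:
    """Build one part's balanced training set.

    Rows are ordered: original positives, synthetic positives, sampled
    negatives.  The negative target is ``ratio * (1 + fp) * n_pos``; if the
    part holds fewer negatives, all of them are used.  Deterministic given
    (master_seed, part_index).
    """
    pos_idx = dataset.positive_indices
    n_pos = len(pos_idx)
    if n_pos == 0:
        raise ConfigurationError("training requires at least one positive sample")
    rng = part_seed(master_seed, part_index)
    positives = dataset.features[pos_idx]
    synthetic = smote_oversample(positives, h.fp, h.k, rng, neighbor_index=neighbor_index)
    target = h.ratio * (1 + h.fp) * n_pos
    sampled = undersample_negatives(np.asarray(part_negatives), target, rng)
    X = np.vstack([positives, synthetic, dataset.features[sampled]])
    n_syn, n_neg = len(synthetic), len(sampled)
    y = np.concatenate(
        [np.ones(n_pos + n_syn, dtype=np.int8), np.zeros(n_neg, dtype=np.int8)]
    )
    provenance = np.concatenate(
        [
            np.full(n_pos, PROV_ORIGINAL_POSITIVE),
            np.full(n_syn, PROV_SYNTHETIC_POSITIVE),
            np.full(n_neg, PROV_SAMPLED_NEGATIVE),
        ]
    )
    return PartTrainingSet(X=X, y=y, provenance=provenance, part_index=part_index)
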