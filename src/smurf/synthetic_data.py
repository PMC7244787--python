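"""Synthetic imbalanced datasets with spherical Gaussian features.

Emulates the benchmark generator for highly imbalanced variant data: every
feature is an independent Gaussian; negatives are N(0, sigma^2) everywhere,
positives are shifted by ``effect_size`` on the first ``n_informative``
features (default 4 of 30) and identical to negatives elsewhere.  Class
counts are exact, not stochastic.  Optional contiguous-block band ids and
round-robin category ids support testing of the grouped-CV machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Dataset
from .exceptions import ConfigurationError


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic draw.

    ``effect_size`` is the mean shift (in units of sigma when sigma=1) of
    the informative features for positives; 1.0 gives a learnable but
    non-trivial signal, 0 gives a null dataset.
    """

    n_samples: int
    n_pos: int
    n_features: int = 30
    n_informative: int = 4
    effect_size: float = 1.0
    sigma: float = 1.0
    seed: int = 0
    n_bands: int = 0
    n_categories: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_pos >= self.n_samples:
            raise ConfigurationError(
                f"n_pos must satisfy 1 <= n_pos < n_samples, got n_pos={self.n_pos}, "
                f"n_samples={self.n_samples}"
            )
        if self.n_informative > self.n_features:
            raise ConfigurationError(
                f"n_informative={self.n_informative} exceeds n_features={self.n_features}"
            )
        if self.sigma <= 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")


def generate(spec: SynthSpec) -> Dataset:
    """Draw a dataset according to ``spec``; deterministic given its seed.

    Rows are shuffled so positives are not clustered at the top; band ids,
    when requested, are contiguous blocks over the shuffled order (emulating
    chromosomal locality), and category ids cycle round-robin.
    """
    rng = np.random.default_rng(spec.seed)
    n_neg = spec.n_samples - spec.n_pos
    features = rng.normal(0.0, spec.sigma, size=(spec.n_samples, spec.n_features))
    labels = np.zeros(spec.n_samples, dtype=np.int8)
    labels[:spec.n_pos] = 1
    features[:spec.n_pos, :spec.n_informative] += spec.effect_size
    order = rng.permutation(spec.n_samples)
    features, labels = features[order], labels[order]
    band_ids = None
    if spec.n_bands > 0:
        if spec.n_bands > spec.n_samples:
            raise ConfigurationError(
                f"n_bands={spec.n_bands} exceeds n_samples={spec.n_samples}"
            )
        blocks = np.array_split(np.arange(spec.n_samples), spec.n_bands)
        band_ids = np.empty(spec.n_samples, dtype=object)
        for b, block in enumerate(blocks):
            band_ids[block] = f"band{b:04d}"
        band_ids = band_ids.astype(str)
    category_ids = None
    if spec.n_categories > 0:
        category_ids = np.array(
            [f"cat{i % spec.n_categories}" for i in range(spec.n_samples)]
        )
    return Dataset(
        features=features, labels=labels, band_ids=band_ids, category_ids=category_ids
    )


def imbalance_ratio(dataset: Dataset) -> float:
    """Negatives per positive."""
    if dataset.n_positives == 0:
        raise ConfigurationError("imbalance ratio undefined: no positive samples")
    return dataset.n_negatives / dataset.n_positives


def format_imbalance(ratio: float) -> str:
    """Render a negatives-per-positive ratio as ``\"1:x\"``.

    Ratios >= 100 are rounded to the nearest hundred (the convention used in
    published dataset summaries); smaller ratios use the nearest integer.
    """
    if ratio < 0:
        raise ConfigurationError(f"imbalance ratio must be >= 0, got {ratio}")
    if ratio >= 100:
        rounded = int(round(ratio / 100.0) * 100)
    else:
        rounded = int(round(ratio))
    return f"1:{rounded:,}"
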