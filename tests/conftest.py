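import numpy as np
import pytest

from smurf import Dataset, HyperParams, SynthSpec, generate


@pytest.fixture
def tiny_dataset() -> Dataset:
    """12 samples, 3 positives, 2 features — small enough to audit by hand."""
    rng = np.random.default_rng(0)
    features = rng.normal(size=(12, 2))
    labels = np.zeros(12, dtype=int)
    labels[[0, 5, 9]] = 1
    return Dataset(features=features, labels=labels)


@pytest.fixture
def signal_dataset() -> Dataset:
    """Imbalanced dataset with a strong learnable signal (effect 2, 1:49)."""
    return generate(
        SynthSpec(n_samples=1500, n_pos=30, effect_size=2.0, seed=7, n_bands=40, n_categories=3)
    )


@pytest.fixture
def small_params() -> HyperParams:
    return HyperParams(n_parts=4, fp=2, ratio=2, k=3, n_trees=10, m_try=2)
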