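import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smurf import Dataset, HyperParams
from smurf.exceptions import ConfigurationError
from smurf.sampling import (
    assemble_part,
    part_seed,
    partition_negatives,
    smote_neighbor_table,
    smote_oversample,
    undersample_negatives,
)

from ._oracles import smote_row_valid


def _dataset(n_pos, n_neg, d=3, seed=0):
    rng = np.random.default_rng(seed)
    features = rng.normal(size=(n_pos + n_neg, d))
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return Dataset(features=features, labels=labels)


class TestPartitionNegatives:
    def test_single_part_is_identity(self):
        d = _dataset(2, 10)
        parts = partition_negatives(d, 1, seed=0)
        assert len(parts) == 1
        assert set(parts[0]) == set(d.negative_indices)

    @given(n_neg=st.integers(5, 60), n_parts=st.integers(1, 5), seed=st.integers(0, 10))
    @settings(max_examples=40, deadline=None)
    def test_disjoint_cover_with_balanced_sizes(self, n_neg, n_parts, seed):
        d = _dataset(2, n_neg)
        parts = partition_negatives(d, n_parts, seed=seed)
        sizes = [len(p) for p in parts]
        assert max(sizes) - min(sizes) <= 1
        union = np.concatenate(parts)
        assert len(union) == len(set(union)) == n_neg
        assert set(union) == set(d.negative_indices)

    def test_more_parts_than_negatives_rejected(self):
        with pytest.raises(ConfigurationError):
            partition_negatives(_dataset(1, 2), 5, seed=0)

    def test_deterministic_given_seed(self):
        d = _dataset(2, 30)
        a = partition_negatives(d, 3, seed=9)
        b = partition_negatives(d, 3, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestSmote:
    def test_count_is_fp_per_positive(self):
        pos = np.random.default_rng(0).normal(size=(5, 4))
        out = smote_oversample(pos, fp=2, k=3, rng=np.random.default_rng(1))
        assert out.shape == (10, 4)

    def test_fp_zero_gives_empty_matrix(self):
        pos = np.ones((3, 2))
        out = smote_oversample(pos, fp=0, k=1, rng=np.random.default_rng(0))
        assert out.shape == (0, 2)

    def test_two_point_geometry(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0]])
        out = smote_oversample(pos, fp=3, k=1, rng=np.random.default_rng(2))
        assert out.shape == (6, 2)
        assert np.all(out[:, 1] == 0)
        assert np.all((out[:, 0] >= 0) & (out[:, 0] <= 1))

    def test_requires_two_positives(self):
        with pytest.raises(ConfigurationError, match=">=2 positives"):
            smote_oversample(np.ones((1, 2)), fp=1, k=1, rng=np.random.default_rng(0))

    def test_k_clamped_when_exceeding_pool(self):
        pos = np.random.default_rng(3).normal(size=(3, 2))
        out = smote_oversample(pos, fp=2, k=10, rng=np.random.default_rng(4))
        assert out.shape == (6, 2)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_segment_membership_oracle(self, k):
        """Every synthetic row lies on a segment between a positive and one
        of its brute-force k nearest positive neighbours."""
        rng = np.random.default_rng(5)
        pos = rng.normal(size=(20, 4))
        fp = 4
        out = smote_oversample(pos, fp=fp, k=k, rng=np.random.default_rng(6))
        for row in range(out.shape[0]):
            source = row // fp  # rows are emitted fp-per-positive in order
            assert smote_row_valid(out[row], pos, source, k)

    def test_neighbor_table_matches_bruteforce(self):
        from ._oracles import brute_knn

        pos = np.random.default_rng(7).normal(size=(15, 3))
        table = smote_neighbor_table(pos, 4)
        for i in range(15):
            assert set(table[i]) == set(brute_knn(pos, i, 4))


class TestUndersample:
    def test_min_rule_returns_all_when_short(self):
        out = undersample_negatives(np.arange(5), 50, np.random.default_rng(0))
        assert set(out) == set(range(5))

    def test_target_zero_empty(self):
        out = undersample_negatives(np.arange(10), 0, np.random.default_rng(0))
        assert len(out) == 0

    def test_sample_without_replacement(self):
        out = undersample_negatives(np.arange(1000), 600, np.random.default_rng(1))
        assert len(out) == 600 == len(set(out))


class TestAssemblePart:
    def test_counts_follow_fp_and_ratio(self):
        d = _dataset(100, 1000)
        h = HyperParams(n_parts=1, fp=1, ratio=1, k=5, n_trees=1, m_try=1)
        part = assemble_part(d, d.negative_indices, h, master_seed=0, part_index=0)
        assert part.n_positives == 200 and part.n_negatives == 200
        assert part.X.shape[0] == 400

    def test_balance_ratio_exact_when_enough_negatives(self):
        d = _dataset(50, 2000)
        h = HyperParams(n_parts=1, fp=2, ratio=2, k=5, n_trees=1, m_try=1)
        part = assemble_part(d, d.negative_indices, h, master_seed=1, part_index=0)
        assert part.n_negatives / part.n_positives == h.ratio

    def test_shortfall_uses_all_available(self):
        d = _dataset(3, 2)
        h = HyperParams(n_parts=1, fp=1, ratio=1, k=2, n_trees=1, m_try=1)
        part = assemble_part(d, d.negative_indices, h, master_seed=0, part_index=0)
        assert part.n_positives == 6 and part.n_negatives == 2

    def test_provenance_counts(self):
        d = _dataset(10, 100)
        h = HyperParams(n_parts=1, fp=3, ratio=1, k=3, n_trees=1, m_try=1)
        part = assemble_part(d, d.negative_indices, h, master_seed=2, part_index=0)
        prov = list(part.provenance)
        assert prov.count("original_positive") == 10
        assert prov.count("synthetic_positive") == 30
        assert prov.count("sampled_negative") == 40

    def test_bit_identical_for_same_seed_and_part(self):
        d = _dataset(10, 100)
        h = HyperParams(n_parts=1, fp=2, ratio=2, k=3, n_trees=1, m_try=1)
        a = assemble_part(d, d.negative_indices, h, master_seed=5, part_index=3)
        b = assemble_part(d, d.negative_indices, h, master_seed=5, part_index=3)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)

    def test_part_streams_independent_of_each_other(self):
        states = [part_seed(7, i).integers(2**32) for i in range(4)]
        assert len(set(states)) == 4
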