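"""Extraction pipeline: operator structure, windows, ranks, transition counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mountpat.core import (
    EEGSegment,
    MountPatExtractor,
    accumulate_transition_table,
    apply_mount_trans,
    build_rank_sequences,
    build_transform_matrix,
    channel_rank,
    create_strided_blocks,
    extract_features,
    feature_length,
    n_blocks,
)
from ._oracles import brute_force_features, enumerate_maps, rank_desc

# The fixed 15x5 operator: identity block then all pairwise differences
# (i, j), i < j, lexicographic, +1 at i and -1 at j.
T5_EXPECTED = np.array(
    [
        [1, 0, 0, 0, 0],
        [0, 1, 0, 0, 0],
        [0, 0, 1, 0, 0],
        [0, 0, 0, 1, 0],
        [0, 0, 0, 0, 1],
        [1, -1, 0, 0, 0],
        [1, 0, -1, 0, 0],
        [1, 0, 0, -1, 0],
        [1, 0, 0, 0, -1],
        [0, 1, -1, 0, 0],
        [0, 1, 0, -1, 0],
        [0, 1, 0, 0, -1],
        [0, 0, 1, -1, 0],
        [0, 0, 1, 0, -1],
        [0, 0, 0, 1, -1],
    ]
)


class TestTransformMatrix:
    def test_default_operator_is_the_fixed_15x5_matrix(self):
        assert np.array_equal(build_transform_matrix(5), T5_EXPECTED)

    def test_smallest_case(self):
        assert np.array_equal(
            build_transform_matrix(2), [[1, 0], [0, 1], [1, -1]]
        )

    @pytest.mark.parametrize(
        "n,rows", [(3, 6), (4, 10), (5, 15), (6, 21), (7, 28)]
    )
    def test_output_map_counts(self, n, rows):
        assert build_transform_matrix(n).shape == (rows, n)

    @given(st.integers(min_value=2, max_value=8))
    @settings(deadline=None)
    def test_row_structure(self, n):
        T = build_transform_matrix(n)
        assert np.array_equal(T[:n], np.eye(n))
        diff = T[n:]
        assert np.all(diff.sum(axis=1) == 0)
        assert np.all((diff == 1).sum(axis=1) == 1)
        assert np.all((diff == -1).sum(axis=1) == 1)

    def test_rejects_degenerate_n(self):
        with pytest.raises(ValueError):
            build_transform_matrix(1)


class TestStridedBlocks:
    @pytest.mark.parametrize(
        "L,n,s,expected",
        [(512, 5, 1, 508), (512, 5, 2, 254), (5, 5, 1, 1), (12, 5, 3, 3)],
    )
    def test_block_counts(self, L, n, s, expected):
        assert n_blocks(L, n, s) == expected
        X = np.arange(L * 2, dtype=float).reshape(L, 2)
        assert create_strided_blocks(X, n, s).shape == (expected, n, 2)

    def test_block_contents_follow_stride(self):
        X = np.arange(24, dtype=float).reshape(12, 2)
        blocks = create_strided_blocks(X, 5, 3)
        for k, start in enumerate([0, 3, 6]):
            assert np.array_equal(blocks[k], X[start : start + 5])

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            create_strided_blocks(np.zeros((4, 3)), 5, 1)


class TestMountTrans:
    def test_equal_vectors_give_zero_differences(self):
        block = np.tile([1.0, 2.0, 3.0], (5, 1))
        P = apply_mount_trans(block, build_transform_matrix(5))
        assert np.array_equal(P[:5], block)
        assert np.all(P[5:] == 0)

    def test_scalar_inputs_match_pairwise_differences(self):
        block = np.arange(1.0, 6.0).reshape(5, 1)  # v_k = k
        P = apply_mount_trans(block, build_transform_matrix(5)).ravel()
        assert P[5] == -1  # v1 - v2
        assert P[9] == -1  # v2 - v3
        assert P[14] == -1  # v4 - v5
        assert P[8] == -4  # v1 - v5

    def test_map_10_is_second_minus_third(self, rng):
        block = rng.normal(size=(5, 7))
        P = apply_mount_trans(block, build_transform_matrix(5))
        assert np.allclose(P[9], block[1] - block[2])

    def test_matrix_product_equals_enumeration_oracle(self, rng):
        T = build_transform_matrix(5)
        for _ in range(100):
            block = rng.normal(size=(5, 4))
            expected = np.array(enumerate_maps(block.tolist()))
            assert np.array_equal(apply_mount_trans(block, T), expected)

    def test_ragged_block_rejected(self):
        with pytest.raises(ValueError):
            apply_mount_trans(np.zeros((4, 3)), build_transform_matrix(5))


class TestChannelRank:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([3, 2, 1], [1, 2, 3]),
            ([0.2, 0.9, 0.5], [2, 3, 1]),
            ([1, 1, 0], [1, 2, 3]),  # stable tie rule: lower channel first
        ],
    )
    def test_descending_rank(self, p, expected):
        assert channel_rank(np.array(p)).tolist() == expected

    def test_matches_loop_oracle(self, rng):
        for _ in range(50):
            p = rng.normal(size=6)
            assert channel_rank(p).tolist() == rank_desc(p.tolist())

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            channel_rank(np.array([1.0, np.nan]))


class TestRankSequences:
    def test_single_block_sequence_length(self, rng):
        seqs = build_rank_sequences(rng.normal(size=(5, 2)))
        assert seqs.shape == (15, 2)

    def test_full_epoch_sequence_length(self, rng):
        seqs = build_rank_sequences(rng.normal(size=(512, 14)))
        assert seqs.shape == (15, 14 * 508)

    def test_every_slice_is_a_permutation(self, rng):
        nc = 5
        seqs = build_rank_sequences(rng.normal(size=(40, nc)))
        for seq in seqs:
            for i in range(0, seq.size, nc):
                assert sorted(seq[i : i + nc]) == list(range(1, nc + 1))

    def test_constant_segment_ranks_in_channel_order(self):
        seqs = build_rank_sequences(np.ones((10, 4)))
        assert np.array_equal(seqs, np.tile([1, 2, 3, 4], (15, 6)))


class TestTransitionTable:
    def test_single_symbol_run(self):
        counts = accumulate_transition_table(np.array([1, 1, 1, 1]), 2)
        assert counts[0, 0] == 3 and counts.sum() == 3

    def test_enumerated_pairs(self):
        counts = accumulate_transition_table(np.array([1, 2, 1, 3]), 3)
        assert counts[0, 1] == 1 and counts[1, 0] == 1 and counts[0, 2] == 1
        assert counts.sum() == 3

    @given(st.lists(st.integers(1, 4), min_size=1, max_size=60))
    @settings(deadline=None)
    def test_conservation(self, seq):
        counts = accumulate_transition_table(np.array(seq), 4)
        assert counts.sum() == len(seq) - 1

    def test_out_of_range_symbol_rejected(self):
        with pytest.raises(ValueError):
            accumulate_transition_table(np.array([1, 5]), 4)


class TestExtractFeatures:
    @pytest.mark.parametrize("nc,length", [(14, 2940), (19, 5415)])
    def test_feature_vector_length(self, rng, nc, length):
        f = extract_features(rng.normal(size=(32, nc)))
        assert f.shape == (length,)
        assert feature_length(5, nc) == length

    def test_matches_brute_force_oracle_on_toy_segment(self):
        seg = np.array(
            [[1, 0], [0, 1], [1, 0], [0, 1], [1, 0], [0, 1], [1, 0]], float
        )
        assert extract_features(seg).tolist() == brute_force_features(seg.tolist())

    def test_matches_brute_force_oracle_on_random_segments(self, rng):
        for nc, L, s in [(2, 7, 1), (3, 12, 2), (4, 9, 1)]:
            seg = rng.normal(size=(L, nc))
            assert (
                extract_features(seg, stride=s).tolist()
                == brute_force_features(seg.tolist(), stride=s)
            )

    def test_per_table_sums_are_conserved(self, rng):
        nc, L = 6, 30
        f = extract_features(rng.normal(size=(L, nc)))
        B = L - 4
        for chunk in f.reshape(15, nc * nc):
            assert chunk.sum() == nc * B - 1

    def test_whole_segment_offset_leaves_features_unchanged(self, rng):
        seg = rng.normal(size=(40, 5))
        assert np.array_equal(
            extract_features(seg), extract_features(seg + 17.3)
        )

    def test_extraction_is_deterministic(self, rng):
        seg = rng.normal(size=(40, 5))
        assert np.array_equal(extract_features(seg), extract_features(seg.copy()))

    @given(st.integers(2, 8))
    @settings(deadline=None, max_examples=7)
    def test_dimension_law(self, n):
        rng = np.random.default_rng(n)
        nc = 3
        f = extract_features(rng.normal(size=(12, nc)), n=n)
        assert f.shape == ((n + n * (n - 1) // 2) * nc * nc,)


class TestSegmentAndEstimator:
    def test_segment_validation(self):
        with pytest.raises(ValueError):
            EEGSegment(np.zeros((10, 1)))  # single channel
        with pytest.raises(ValueError):
            EEGSegment(np.full((10, 3), np.nan))
        with pytest.raises(ValueError):
            EEGSegment(np.zeros((10, 2)), channel_labels=["a", "a"])

    def test_estimator_transforms_a_batch(self, rng):
        segs = [rng.normal(size=(20, 4)) for _ in range(3)]
        ext = MountPatExtractor()
        F = ext.fit_transform(segs)
        assert F.shape == (3, feature_length(5, 4))
        assert ext.n_features_out_ == feature_length(5, 4)
        assert np.array_equal(F[0], extract_features(segs[0]))

    def test_estimator_params_round_trip(self):
        from sklearn.base import clone

        ext = MountPatExtractor(n=3, stride=2)
        assert clone(ext).get_params() == {"n": 3, "stride": 2}
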