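"""Deterministic graph-based feature extraction for multichannel EEG epochs.

The extractor (MountPat) turns a raw ``L x nc`` epoch into a fixed-length
integer feature vector in four steps:

1. slide a window of ``n`` consecutive time samples (stride ``s``) over the
   epoch, giving ``B = floor((L - n)/s) + 1`` blocks of ``n`` channel-vectors;
2. apply a fixed linear operator (the "mountain" transform) mapping the ``n``
   vectors to ``n`` identity copies plus all ``C(n, 2)`` pairwise differences
   — ``R = n + C(n, 2)`` maps per block (15 for the default ``n = 5``);
3. rank the channels of every map by descending amplitude, concatenating the
   per-block permutations into one rank sequence per map (length ``nc * B``);
4. count consecutive-symbol transitions of each rank sequence in an
   ``nc x nc`` table and concatenate the 15 flattened tables, giving a
   feature vector of length ``R * nc**2`` (``15 * nc**2`` by default).

No filtering, artifact removal or amplitude normalisation is applied at any
point: the transform is rank-based, and raw transition counts are the
features (for fixed epoch length the total count per table is constant, so
counts are proportional to transition probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EEGSegment",
    "build_transform_matrix",
    "n_output_maps",
    "feature_length",
    "n_blocks",
    "create_strided_blocks",
    "apply_mount_trans",
    "channel_rank",
    "build_rank_sequences",
    "accumulate_transition_table",
    "extract_features",
    "MountPatExtractor",
]


@dataclass
class EEGSegment:
    """One labelled EEG epoch: an ``L x nc`` amplitude matrix plus metadata.

    Rows are time samples, columns are channels, raw amplitude units.
    """

    data: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    label: object = None
    subject_id: object = None
    sampling_rate_hz: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("segment data must be a 2-D (time x channels) matrix")
        L, nc = self.data.shape
        if nc < 2:
            raise ValueError(f"segment needs at least 2 channels, got {nc}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment contains non-finite values")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(nc)]
        if len(self.channel_labels) != nc:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {nc} channels"
            )
        if len(set(self.channel_labels)) != nc:
            raise ValueError("channel labels must be unique")
        if self.sampling_rate_hz is not None and self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def n_output_maps(n: int) -> int:
    """Number of transform outputs: ``n`` identities + ``C(n, 2)`` differences."""
    return n + comb(n, 2)


def feature_length(n: int, nc: int) -> int:
    """Final feature-vector length ``(n + C(n, 2)) * nc**2``."""
    return n_output_maps(n) * nc * nc


def build_transform_matrix(n: int = 5) -> np.ndarray:
    """Build the fixed ``(n + C(n,2)) x n`` integer transform operator.

    The first ``n`` rows are the identity block; the remaining ``C(n, 2)``
    rows encode the pairwise differences ``v_i - v_j`` for ``i < j`` in
    lexicographic order (+1 in column ``i``, -1 in column ``j``).  The
    operator is fixed and non-trainable.
    """
    if n < 2:
        raise ValueError(f"transform needs n >= 2 input vectors, got n={n}")
    rows = n_output_maps(n)
    T = np.zeros((rows, n), dtype=np.int8)
    T[:n, :n] = np.eye(n, dtype=np.int8)
    for r, (i, j) in enumerate(combinations(range(n), 2), start=n):
        T[r, i] = 1
        T[r, j] = -1
    return T


def n_blocks(L: int, n: int = 5, stride: int = 1) -> int:
    """Number of strided windows: ``floor((L - n)/stride) + 1``."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if L < n:
        raise ValueError(f"segment too short: L={L} < window n={n}")
    return (L - n) // stride + 1


def _as_matrix(segment: EEGSegment | np.ndarray) -> np.ndarray:
    if isinstance(segment, EEGSegment):
        return segment.data
    X = np.asarray(segment, dtype=float)
    if X.ndim != 2:
        raise ValueError("segment must be a 2-D (time x channels) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("segment contains non-finite values")
    return X


def create_strided_blocks(
    segment: EEGSegment | np.ndarray, n: int = 5, stride: int = 1
) -> np.ndarray:
    """Extract overlapping windows of ``n`` consecutive time samples.

    Returns an array of shape ``(B, n, nc)``; block ``k`` (0-based) holds
    rows ``k*stride .. k*stride + n - 1`` of the segment.
    """
    X = _as_matrix(segment)
    L = X.shape[0]
    B = n_blocks(L, n, stride)
    windows = np.lib.stride_tricks.sliding_window_view(X, n, axis=0)
    # sliding_window_view yields (L-n+1, nc, n); subsample by stride and
    # put the window axis in the middle.
    return np.ascontiguousarray(windows[:: stride][:B].transpose(0, 2, 1))


def apply_mount_trans(block: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Apply the transform operator to one block: ``P = T @ block``.

    ``block`` is ``(n, nc)``; the result is ``(n + C(n,2), nc)`` with the
    identity maps first and the pairwise differences after.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ValueError("block must be a 2-D (n x nc) matrix")
    if block.shape[0] != T.shape[1]:
        raise ValueError(
            f"block has {block.shape[0]} vectors but operator expects {T.shape[1]}"
        )
    return T.astype(float) @ block


def channel_rank(p: np.ndarray) -> np.ndarray:
    """Channel indices (1-based) sorted by descending value.

    Ties are broken by ascending channel index (stable sort), so a constant
    vector ranks as ``[1, 2, ..., nc]``.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("cannot rank non-finite values")
    return np.argsort(-p, kind="stable") + 1


def build_rank_sequences(
    segment: EEGSegment | np.ndarray,
    T: np.ndarray | None = None,
    n: int = 5,
    stride: int = 1,
) -> np.ndarray:
    """Rank sequences for every transform map, shape ``(R, nc*B)``.

    For map ``u`` the sequence concatenates, block by block, the 1-based
    channel permutation ranking that block's transformed vector by
    descending amplitude.  Every consecutive ``nc``-slice is therefore a
    permutation of ``1..nc``.
    """
    if T is None:
        T = build_transform_matrix(n)
    else:
        n = T.shape[1]
    blocks = create_strided_blocks(segment, n, stride)  # (B, n, nc)
    P = np.einsum("rn,bnc->brc", T.astype(float), blocks)  # (B, R, nc)
    ranks = np.argsort(-P, axis=2, kind="stable") + 1  # (B, R, nc)
    R = T.shape[0]
    return np.ascontiguousarray(ranks.transpose(1, 0, 2).reshape(R, -1))


def accumulate_transition_table(seq: np.ndarray, nc: int) -> np.ndarray:
    """Count consecutive-symbol transitions of a rank sequence.

    ``counts[a-1, b-1]`` is the number of positions ``q`` with
    ``seq[q] = a`` followed by ``seq[q+1] = b``; the total count equals
    ``len(seq) - 1``.  Transitions crossing block boundaries are counted —
    the sequence is treated as one flat symbol stream.
    """
    seq = np.asarray(seq)
    if seq.size and (seq.min() < 1 or seq.max() > nc):
        raise ValueError(f"sequence symbols must lie in [1, {nc}]")
    counts = np.zeros((nc, nc), dtype=np.int64)
    if seq.size >= 2:
        np.add.at(counts, (seq[:-1] - 1, seq[1:] - 1), 1)
    return counts


def extract_features(
    segment: EEGSegment | np.ndarray, n: int = 5, stride: int = 1
) -> np.ndarray:
    """Full extraction: segment -> integer feature vector of length ``R*nc**2``.

    Each of the ``R = n + C(n,2)`` transition tables is flattened row-major
    (source channel outer, destination channel inner) and the flattened
    tables are concatenated in transform order.  Counts are raw (no
    normalisation).
    """
    X = _as_matrix(segment)
    nc = X.shape[1]
    T = build_transform_matrix(n)
    seqs = build_rank_sequences(X, T, stride=stride)
    return np.concatenate(
        [accumulate_transition_table(seqs[u], nc).ravel() for u in range(T.shape[0])]
    )


class MountPatExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the epoch feature extraction.

    Parameters
    ----------
    n : int, default 5
        Window size (number of consecutive time samples per block); the
        operator emits ``n + C(n, 2)`` maps per block.
    stride : int, default 1
        Step between consecutive windows.  Stride 1 gives maximal overlap
        (``L - n + 1`` blocks); larger strides trade temporal resolution
        for speed.

    The transformer is stateless (the operator is fixed); ``fit`` only
    records input dimensions.  ``transform`` accepts a sequence of
    ``(L, nc)`` matrices / ``EEGSegment`` objects or a single 3-D array
    ``(n_epochs, L, nc)`` and returns the ``(n_epochs, R*nc**2)`` integer
    feature matrix.
    """

    def __init__(self, n: int = 5, stride: int = 1):
        self.n = n
        self.stride = stride

    def fit(self, X, y=None):
        first = _as_matrix(X[0])
        self.n_channels_ = first.shape[1]
        self.n_features_out_ = feature_length(self.n, self.n_channels_)
        self.transform_matrix_ = build_transform_matrix(self.n)
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack(
            [extract_features(seg, n=self.n, stride=self.stride) for seg in X]
        )

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)
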