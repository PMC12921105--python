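"""Cumulative-weighted iterative NCA feature selection (CWINCA).

Neighbourhood component analysis (NCA) with a diagonal, per-feature weight
vector scores every feature by how much it helps a stochastic leave-one-out
nearest-neighbour classifier.  CWINCA turns those weights into a
self-organising selector:

1. learn nonnegative per-feature weights ``w`` by gradient ascent on the
   regularised leave-one-out NCA objective;
2. sort features by descending weight, normalise the sorted weights to sum
   one, and take cumulative sums; the smallest prefix reaching the lower
   threshold ``tr1`` (default 0.85) gives the loop *start*, the smallest
   prefix reaching ``tr2`` (default 0.9999) gives the *stop*;
3. for every candidate size ``k`` in ``[start, stop]`` evaluate the top-``k``
   features with an inner stratified cross-validated 1-NN classifier and
   keep the ``k`` with the highest accuracy (ties go to the smallest ``k``).

The selected set is always a prefix of the weight-sorted order, so the
selector both shrinks the feature space and ranks what survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeatureWeights",
    "SelectionRange",
    "SelectionResult",
    "nca_weights",
    "cumulative_range",
    "iterative_select",
    "CWINCASelector",
]


@dataclass
class FeatureWeights:
    """Nonnegative per-feature NCA weights and the descending-weight order."""

    weights: np.ndarray
    order: np.ndarray  # 0-based feature indices sorted by descending weight

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.order = np.asarray(self.order, dtype=int)


@dataclass
class SelectionRange:
    """Candidate subset sizes [start, stop] from cumulative-weight thresholds."""

    start: int
    stop: int
    tr1: float = 0.85
    tr2: float = 0.9999


@dataclass
class SelectionResult:
    """Chosen feature subset.

    ``selected`` holds 1-based original feature indices in descending-weight
    order (1-based to match the serialised index convention used throughout;
    subtract 1 for NumPy indexing).
    """

    selected: list[int]
    k: int
    inner_accuracy: float
    weights: FeatureWeights | None = field(default=None, repr=False)


def nca_weights(
    features: np.ndarray,
    labels: np.ndarray,
    *,
    iterations: int = 100,
    learning_rate: float = 0.1,
    regularization: float | str = "auto",
    kernel_width: float = 1.0,
    standardize: bool = True,
    tol: float = 1e-6,
    seed: int = 1,
) -> FeatureWeights:
    """Learn per-feature NCA weights by batch gradient ascent.

    The distance between samples is the weighted L1 metric
    ``d(i, j) = sum_f w_f**2 |x_if - x_jf|``; sample ``i`` picks neighbour
    ``j`` with probability ``p_ij ∝ exp(-d_ij / sigma)`` and the objective
    is the expected leave-one-out accuracy ``sum_i sum_{j in class(i)} p_ij``
    minus an L2 penalty ``lam * sum_f w_f**2`` that drives the weights of
    uninformative features towards zero.

    Parameters
    ----------
    iterations : maximum gradient steps (batch gradient with an adaptive
        step: grow on improvement, halve and retry on a worse objective).
    regularization : the penalty ``lam``; ``"auto"`` uses ``1 / n_samples``.
    kernel_width : softmax temperature ``sigma`` (features are z-scored
        internally by default, so 1.0 is a natural scale).
    standardize : z-score features (training statistics) before optimising;
        used only for weight learning — selection returns indices and
        downstream consumers see raw feature values.
    seed : recorded for API symmetry; the batch optimiser is deterministic.

    Returns the weight vector (on the original feature order) and the
    descending-weight ranking.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (samples x features) matrix")
    N, F = X.shape
    if y.shape[0] != N:
        raise ValueError("labels length does not match number of samples")
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to learn NCA weights")
    counts = np.bincount(y_enc)
    if counts.min() < 2:
        raise ValueError("every class needs at least two samples")

    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    lam = 1.0 / N if regularization == "auto" else float(regularization)
    sigma = float(kernel_width)

    # Pairwise per-feature absolute differences, flattened over (i, j).
    # float32 halves memory traffic; counts are exact in float32 range.
    D = np.abs(X[:, None, :] - X[None, :, :]).reshape(N * N, F).astype(np.float32)
    same = (y_enc[:, None] == y_enc[None, :]).astype(np.float64)
    np.fill_diagonal(same.reshape(N, N), 0.0)

    w = np.ones(F)
    step = float(learning_rate)
    prev_obj = -np.inf
    best_w = w.copy()
    best_obj = -np.inf

    def objective_and_grad(w: np.ndarray):
        w2 = (w * w).astype(np.float32)
        dist = (D @ w2).reshape(N, N).astype(np.float64)
        np.fill_diagonal(dist, np.inf)
        logits = -dist / sigma
        logits -= logits.max(axis=1, keepdims=True)
        ker = np.exp(logits)
        ker_sum = ker.sum(axis=1, keepdims=True)
        p = ker / ker_sum  # p[i, j]: prob. i picks j as neighbour
        xi_i = (p * same).sum(axis=1)  # expected LOO hit rate per sample
        obj = xi_i.sum() - lam * np.dot(w, w)
        # d obj / d dist_ij = (1/sigma) * p_ij * (xi_i - same_ij)
        coeff = (p * (xi_i[:, None] - same) / sigma).astype(np.float32)
        grad = 2.0 * w * (coeff.reshape(-1) @ D).astype(np.float64) - 2.0 * lam * w
        return obj, grad

    obj, grad = objective_and_grad(w)
    for _ in range(iterations):
        if obj > best_obj:
            best_obj, best_w = obj, w.copy()
        w_new = w + step * grad
        new_obj, new_grad = objective_and_grad(w_new)
        if new_obj >= obj:
            if abs(new_obj - obj) < tol * max(1.0, abs(obj)):
                w, obj = w_new, new_obj
                break
            step *= 1.05
            w, obj, grad = w_new, new_obj, new_grad
        else:
            step *= 0.5
            if step < 1e-12:
                break
    if obj > best_obj:
        best_obj, best_w = obj, w.copy()

    weights = best_w * best_w  # report the effective (squared) scale, >= 0
    order = np.argsort(-weights, kind="stable")
    return FeatureWeights(weights=weights, order=order)


def cumulative_range(
    w: FeatureWeights | np.ndarray, tr1: float = 0.85, tr2: float = 0.9999
) -> SelectionRange:
    """Loop bounds from the cumulative distribution of sorted weights.

    Sorted weights are normalised to sum one; ``start`` is the smallest
    prefix length whose cumulative mass reaches ``tr1``, ``stop`` the
    smallest reaching ``tr2``.
    """
    if not (0.0 < tr1 < tr2 <= 1.0):
        raise ValueError(f"need 0 < tr1 < tr2 <= 1, got tr1={tr1}, tr2={tr2}")
    weights = w.weights if isinstance(w, FeatureWeights) else np.asarray(w, float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all-zero weights: nothing to rank")
    sorted_w = np.sort(weights)[::-1]
    cum = np.cumsum(sorted_w) / total
    eps = 1e-12  # float-safe threshold comparison
    start = int(np.argmax(cum >= tr1 - eps)) + 1
    reached = cum >= tr2 - eps
    stop = int(np.argmax(reached)) + 1 if reached.any() else weights.size
    return SelectionRange(start=start, stop=stop, tr1=tr1, tr2=tr2)


def _nn1_cv_accuracies(
    X: np.ndarray,
    y_enc: np.ndarray,
    order: np.ndarray,
    start: int,
    stop: int,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Inner 1-NN CV accuracy for every prefix size k in [start, stop].

    Exploits that the top-(k+1) squared Euclidean distance matrix is the
    top-k matrix plus one feature's contribution, so the whole sweep costs
    O(stop * N^2) instead of O(stop^2 * N^2).
    """
    N = X.shape[0]
    d2 = np.zeros((N, N))
    accs = np.empty(stop - start + 1)
    for k in range(1, stop + 1):
        col = X[:, order[k - 1]]
        diff = col[:, None] - col[None, :]
        d2 += diff * diff
        if k < start:
            continue
        correct = 0
        for train_idx, test_idx in folds:
            sub = d2[np.ix_(test_idx, train_idx)]
            pred = y_enc[train_idx[np.argmin(sub, axis=1)]]
            correct += int((pred == y_enc[test_idx]).sum())
        accs[k - start] = correct / N
    return accs


def iterative_select(
    features: np.ndarray,
    labels: np.ndarray,
    srange: SelectionRange,
    w: FeatureWeights,
    *,
    inner_cv_folds: int = 10,
    inner_k: int = 1,
    seed: int = 1,
) -> SelectionResult:
    """Greedy accuracy-maximising choice of the top-k feature prefix.

    For each ``k`` in ``[start, stop]`` the top-``k`` features by weight are
    scored by stratified ``inner_cv_folds``-fold cross-validated 1-NN
    accuracy (Euclidean, raw feature values); the ``k`` with the highest
    accuracy wins, ties going to the smallest ``k``.
    """
    if inner_k != 1:
        raise NotImplementedError("inner evaluation classifier is fixed to 1-NN")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    N, F = X.shape
    start, stop = srange.start, srange.stop
    if stop > F:
        warnings.warn(
            f"selection range stop={stop} exceeds {F} features; clipping",
            stacklevel=2,
        )
        stop = F
        start = min(start, F)
    _, y_enc = np.unique(y, return_inverse=True)
    n_splits = min(inner_cv_folds, int(np.bincount(y_enc).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(X, y_enc)]
    accs = _nn1_cv_accuracies(X, y_enc, w.order, start, stop, folds)
    best = int(np.argmax(accs))  # argmax takes the first (smallest k) on ties
    k = start + best
    selected = [int(i) + 1 for i in w.order[:k]]
    return SelectionResult(
        selected=selected, k=k, inner_accuracy=float(accs[best]), weights=w
    )


class CWINCASelector(SelectorMixin, BaseEstimator):
    """Cumulative-weighted iterative NCA feature selector.

    Learns diagonal NCA weights on the training data, bounds the candidate
    subset sizes by the cumulative-weight thresholds ``tr1``/``tr2`` and
    picks the size whose top-weighted prefix maximises inner stratified
    cross-validated 1-NN accuracy.  ``transform`` keeps the selected
    columns (raw values, no scaling).

    Attributes (after ``fit``)
    --------------------------
    weights_ : per-feature NCA weights (original order)
    ranking_ : 0-based feature indices by descending weight
    range_ : the cumulative-weight ``SelectionRange``
    selection_ : the full ``SelectionResult`` (1-based indices)
    n_selected_ : chosen subset size
    """

    def __init__(
        self,
        tr1: float = 0.85,
        tr2: float = 0.9999,
        iterations: int = 100,
        learning_rate: float = 0.1,
        regularization: float | str = "auto",
        kernel_width: float = 1.0,
        inner_cv_folds: int = 10,
        inner_k: int = 1,
        random_state: int = 1,
    ):
        self.tr1 = tr1
        self.tr2 = tr2
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.regularization = regularization
        self.kernel_width = kernel_width
        self.inner_cv_folds = inner_cv_folds
        self.inner_k = inner_k
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        fw = nca_weights(
            X,
            y,
            iterations=self.iterations,
            learning_rate=self.learning_rate,
            regularization=self.regularization,
            kernel_width=self.kernel_width,
            seed=self.random_state,
        )
        srange = cumulative_range(fw, self.tr1, self.tr2)
        sel = iterative_select(
            X,
            y,
            srange,
            fw,
            inner_cv_folds=self.inner_cv_folds,
            inner_k=self.inner_k,
            seed=self.random_state,
        )
        self.n_features_in_ = X.shape[1]
        self.weights_ = fw.weights
        self.ranking_ = fw.order
        self.range_ = srange
        self.selection_ = sel
        self.n_selected_ = sel.k
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[[i - 1 for i in sel.selected]] = True
        self.support_ = mask
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
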