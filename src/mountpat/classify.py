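"""Self-organising kNN ensemble (tkNN) with iterative majority voting.

A plain k-nearest-neighbour classifier is swept over a small parameter grid
(neighbour count k = 1..5 crossed with three distance weightings: equal,
1/d and 1/d**2 — 15 configurations), each configuration scored by inner
stratified cross-validation on the training data.  The out-of-fold
prediction vectors are then combined by iterative majority voting (IMV):
sort the configurations by accuracy and, for every ensemble size j in
3..20, take the elementwise majority of the top-j prediction vectors.  The
single best outcome — parameter-based or voted — wins, and that winning
recipe is what ``predict`` applies to new data.  The classifier therefore
organises itself: no parameter is chosen by the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "WEIGHTINGS",
    "PredictionOutcome",
    "knn_predict",
    "parameter_sweep",
    "iterative_majority_vote",
    "select_best",
    "TkNNClassifier",
]

WEIGHTINGS = ("equal", "inverse", "squared_inverse")


@dataclass
class PredictionOutcome:
    """One candidate outcome: a parameter setting or a voted ensemble.

    ``parameter_id`` is ``(k, weighting)`` for grid outcomes and
    ``("vote", j)`` for a majority vote over the top-``j`` most accurate
    grid outcomes.
    """

    parameter_id: tuple
    predictions: np.ndarray
    accuracy: float

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions)


def _vote_weights(dist: np.ndarray, weighting: str) -> np.ndarray:
    """Per-neighbour vote weights; exact hits dominate distance weighting."""
    if weighting == "equal":
        return np.ones_like(dist)
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")
    with np.errstate(divide="ignore"):
        w = 1.0 / dist if weighting == "inverse" else 1.0 / (dist * dist)
    # A zero-distance neighbour gets infinite weight: it alone votes.
    inf_rows = np.isinf(w).any(axis=1)
    if inf_rows.any():
        w[inf_rows] = np.isinf(w[inf_rows]).astype(float)
    return w


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    k: int,
    weighting: str = "equal",
) -> np.ndarray:
    """k-nearest-neighbour prediction under Euclidean distance.

    Votes are summed per class with the chosen weighting; vote ties break
    to the lowest class label (sorted label order).
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if k > train_X.shape[0]:
        raise ValueError(f"k={k} exceeds {train_X.shape[0]} training samples")
    classes, y_enc = np.unique(train_y, return_inverse=True)
    dist = pairwise_distances(test_X, train_X, metric="euclidean")
    # k smallest distances, deterministically ordered (distance, then index)
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]
    nn_dist = np.take_along_axis(dist, nn, axis=1)
    w = _vote_weights(nn_dist, weighting)
    votes = np.zeros((test_X.shape[0], classes.size))
    for c in range(classes.size):
        votes[:, c] = np.where(y_enc[nn] == c, w, 0.0).sum(axis=1)
    return classes[np.argmax(votes, axis=1)]  # argmax: first max = lowest label


def parameter_sweep(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5),
    weightings: tuple[str, ...] = WEIGHTINGS,
) -> list[PredictionOutcome]:
    """One outcome per (k, weighting) grid cell, scored on the validation set."""
    val_y = np.asarray(val_y)
    outcomes = []
    for k, weighting in product(k_values, weightings):
        pred = knn_predict(train_X, train_y, val_X, k, weighting)
        acc = float(np.mean(pred == val_y))
        outcomes.append(PredictionOutcome((k, weighting), pred, acc))
    return outcomes


def _majority(preds: np.ndarray, tiebreak: np.ndarray) -> np.ndarray:
    """Columnwise majority of a (j, n_samples) prediction stack.

    Ties go to ``tiebreak`` (the single most accurate outcome's prediction).
    """
    classes = np.unique(preds)
    counts = np.stack([(preds == c).sum(axis=0) for c in classes])  # (C, n)
    top = counts.max(axis=0)
    winner = classes[np.argmax(counts, axis=0)]
    tied = (counts == top).sum(axis=0) > 1
    out = winner.copy()
    out[tied] = tiebreak[tied]
    return out


def iterative_majority_vote(
    outcomes: list[PredictionOutcome],
    y_true: np.ndarray,
    j_min: int = 3,
    j_max: int = 20,
) -> list[PredictionOutcome]:
    """Voted outcomes over the top-j most accurate predictors, j in [j_min, j_max].

    Outcomes are sorted by descending accuracy (stable, so earlier outcomes
    win accuracy ties); each voted outcome is the elementwise majority of
    the top-j prediction vectors, vote ties resolved by the most accurate
    single outcome.  Returns the voted outcomes only, in ascending j.
    """
    y_true = np.asarray(y_true)
    if len(outcomes) < j_min:
        warnings.warn(
            f"only {len(outcomes)} outcomes; need >= {j_min} for voting — skipped",
            stacklevel=2,
        )
        return []
    order = np.argsort([-o.accuracy for o in outcomes], kind="stable")
    ranked = [outcomes[i] for i in order]
    stack = np.stack([o.predictions for o in ranked])
    best_pred = ranked[0].predictions
    voted = []
    for j in range(j_min, min(j_max, len(ranked)) + 1):
        pred = _majority(stack[:j], best_pred)
        acc = float(np.mean(pred == y_true))
        voted.append(PredictionOutcome(("vote", j), pred, acc))
    return voted


def select_best(outcomes: list[PredictionOutcome]) -> PredictionOutcome:
    """Greedy argmax of accuracy; ties go to the earliest generated outcome."""
    if not outcomes:
        raise ValueError("no outcomes to select from")
    best = outcomes[0]
    for o in outcomes[1:]:
        if o.accuracy > best.accuracy:
            best = o
    return best


@dataclass
class _FittedEnsemble:
    """Winning recipe: grid configs in accuracy order and the chosen outcome."""

    ranked_configs: list[tuple]  # (k, weighting), descending inner accuracy
    best_id: tuple  # (k, weighting) or ("vote", j)


class TkNNClassifier(ClassifierMixin, BaseEstimator):
    """Self-organising kNN ensemble with iterative majority voting.

    ``fit`` scores every (k, weighting) configuration by inner stratified
    ``inner_cv_folds``-fold cross-validation on the training data (pooled
    out-of-fold predictions), adds majority-voted outcomes over the top-j
    configurations for j in ``[j_min, j_max]``, and keeps the single best
    outcome.  ``predict`` refits the winning configuration — or the winning
    voted ensemble — on the full training data.

    Attributes (after ``fit``)
    --------------------------
    classes_ : sorted class labels
    outcomes_ : all candidate outcomes (grid then voted) with accuracies
    best_outcome_ : the winning ``PredictionOutcome``
    inner_accuracy_ : its inner-CV accuracy
    """

    def __init__(
        self,
        k_values: tuple[int, ...] = (1, 2, 3, 4, 5),
        weightings: tuple[str, ...] = WEIGHTINGS,
        j_min: int = 3,
        j_max: int = 20,
        inner_cv_folds: int = 5,
        random_state: int = 1,
    ):
        self.k_values = k_values
        self.weightings = weightings
        self.j_min = j_min
        self.j_max = j_max
        self.inner_cv_folds = inner_cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._X = X
        self._y = y
        n_splits = max(2, min(self.inner_cv_folds, np.bincount(
            np.unique(y, return_inverse=True)[1]).min()))
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=self.random_state
        )
        grid = list(product(self.k_values, self.weightings))
        oof = {pid: np.empty(len(y), dtype=y.dtype) for pid in grid}
        for tr, te in skf.split(X, y):
            k_cap = len(tr)
            for k, weighting in grid:
                oof[(k, weighting)][te] = knn_predict(
                    X[tr], y[tr], X[te], min(k, k_cap), weighting
                )
        outcomes = [
            PredictionOutcome(pid, oof[pid], float(np.mean(oof[pid] == y)))
            for pid in grid
        ]
        voted = iterative_majority_vote(outcomes, y, self.j_min, self.j_max)
        all_outcomes = outcomes + voted
        best = select_best(all_outcomes)
        order = np.argsort([-o.accuracy for o in outcomes], kind="stable")
        self.outcomes_ = all_outcomes
        self.best_outcome_ = best
        self.inner_accuracy_ = best.accuracy
        self._ensemble = _FittedEnsemble(
            ranked_configs=[outcomes[i].parameter_id for i in order],
            best_id=best.parameter_id,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "best_outcome_")
        X = np.asarray(X, dtype=float)
        ens = self._ensemble
        k_cap = len(self._y)
        if ens.best_id[0] == "vote":
            j = ens.best_id[1]
            preds = np.stack(
                [
                    knn_predict(self._X, self._y, X, min(k, k_cap), weighting)
                    for k, weighting in ens.ranked_configs[:j]
                ]
            )
            return _majority(preds, preds[0])
        k, weighting = ens.best_id
        return knn_predict(self._X, self._y, X, min(k, k_cap), weighting)
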