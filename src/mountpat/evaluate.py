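"""Cross-validation harness and the multiclass metric suite.

Two validation protocols are supported:

* sample-wise stratified k-fold (default 10 folds) — epochs assigned to
  folds at random, class proportions preserved;
* leave-one-subject-out (LOSO) — all epochs of one subject held out per
  fold, testing cross-subject generalisation.

Feature selection and classifier tuning are embedded inside the fold loop:
in every fold the selector and the classifier's inner parameter sweep see
only the training partition, and the held-out fold is touched exactly once,
for prediction.  Each fold's log records the training, selection and test
index sets so the no-leakage property is auditable after the fact.

Feature extraction itself is deterministic and label-free, so features may
be computed once per epoch before the fold loop without leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import TkNNClassifier
from .select import CWINCASelector, SelectionResult

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "FoldLog",
    "make_folds",
    "compute_metrics",
    "cross_validate_pipeline",
    "audit_no_leakage",
]


@dataclass
class FoldPlan:
    """Fold id per sample, plus the protocol that produced it."""

    mode: str  # "stratified_kfold" | "loso"
    assignments: np.ndarray
    k: int

    def split(self):
        """Yield (train_indices, test_indices) per fold."""
        for f in range(self.k):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield train, test


@dataclass
class MetricsReport:
    """Confusion matrix and the derived multiclass metrics (fractions in [0, 1])."""

    confusion: np.ndarray
    class_labels: list
    accuracy: float
    recall: float  # macro
    precision: float  # macro
    f1: float  # macro
    geometric_mean: float  # geometric mean of per-class recalls
    balanced_accuracy: float
    mcc: float
    kappa: float
    per_class_recall: np.ndarray = field(repr=False, default=None)
    per_class_precision: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_labels": [str(c) for c in self.class_labels],
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "geometric_mean": self.geometric_mean,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "kappa": self.kappa,
        }


@dataclass
class FoldLog:
    """Audit record for one fold."""

    fold: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    selection_indices: np.ndarray  # samples the selector/tuner saw
    selection: SelectionResult
    best_parameter: tuple
    test_accuracy: float


def make_folds(
    labels: np.ndarray,
    mode: str = "stratified_kfold",
    k: int = 10,
    seed: int = 1,
    subjects: np.ndarray | None = None,
) -> FoldPlan:
    """Deterministic fold assignment.

    Stratified mode shuffles epochs into ``k`` folds preserving class
    proportions; LOSO builds one fold per unique subject id (sorted order)
    and requires a subject for every sample.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    assignments = np.empty(n, dtype=int)
    if mode == "loso":
        if subjects is None:
            raise ValueError(
                "LOSO validation requires a subject id for every sample"
            )
        subjects = np.asarray(subjects)
        if subjects.shape[0] != n or any(s is None for s in subjects.tolist()):
            raise ValueError(
                "LOSO validation requires a subject id for every sample"
            )
        uniq = np.unique(subjects)
        for f, s in enumerate(uniq):
            assignments[subjects == s] = f
        return FoldPlan(mode="loso", assignments=assignments, k=len(uniq))
    if mode != "stratified_kfold":
        raise ValueError(f"unknown fold mode {mode!r}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, test) in enumerate(skf.split(np.zeros(n), labels)):
        assignments[test] = f
    return FoldPlan(mode="stratified_kfold", assignments=assignments, k=k)


def compute_metrics(confusion: np.ndarray, class_labels=None) -> MetricsReport:
    """Multiclass metrics from a confusion matrix (rows = true, cols = predicted).

    Macro averages are over classes with nonzero support (zero-support
    classes are excluded with a warning); the geometric mean is over
    per-class recalls; balanced accuracy equals macro recall by definition.
    """
    C = np.asarray(confusion, dtype=np.int64)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if (C < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    total = C.sum()
    if total == 0:
        raise ValueError("empty confusion matrix (no evaluated samples)")
    if class_labels is None:
        class_labels = list(range(C.shape[0]))
    t = C.sum(axis=1).astype(float)  # true (support) per class
    p = C.sum(axis=0).astype(float)  # predicted per class
    diag = np.diag(C).astype(float)
    support = t > 0
    if not support.all():
        warnings.warn(
            "classes with zero support excluded from macro averages",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rec = np.where(t > 0, diag / t, np.nan)
        prec = np.where(p > 0, diag / p, 0.0)  # no prediction -> precision 0
    rec_s = rec[support]
    prec_s = prec[support]
    with np.errstate(divide="ignore", invalid="ignore"):
        f1_s = np.where(
            prec_s + rec_s > 0, 2 * prec_s * rec_s / (prec_s + rec_s), 0.0
        )
    macro_rec = float(rec_s.mean())
    gmean = float(np.exp(np.log(np.clip(rec_s, 1e-300, None)).mean())) if (
        rec_s > 0
    ).all() else 0.0
    acc = float(diag.sum() / total)
    # Multiclass Matthews correlation and Cohen's kappa from the confusion
    s = float(total)
    cov_ytyp = diag.sum() * s - float(np.dot(t, p))
    cov_ypyp = s * s - float(np.dot(p, p))
    cov_ytyt = s * s - float(np.dot(t, t))
    denom = np.sqrt(cov_ypyp * cov_ytyt)
    mcc = float(cov_ytyp / denom) if denom > 0 else 0.0
    pe = float(np.dot(t, p)) / (s * s)
    kappa = float((acc - pe) / (1 - pe)) if pe < 1 else 0.0
    return MetricsReport(
        confusion=C,
        class_labels=list(class_labels),
        accuracy=acc,
        recall=macro_rec,
        precision=float(prec_s.mean()),
        f1=float(f1_s.mean()),
        geometric_mean=gmean,
        balanced_accuracy=macro_rec,
        mcc=mcc,
        kappa=kappa,
        per_class_recall=rec,
        per_class_precision=prec,
    )


def cross_validate_pipeline(
    features: np.ndarray,
    labels: np.ndarray,
    *,
    mode: str = "stratified_kfold",
    folds: int = 10,
    seed: int = 1,
    subjects: np.ndarray | None = None,
    selector_params: dict | None = None,
    classifier_params: dict | None = None,
) -> tuple[MetricsReport, list[FoldLog]]:
    """Fold-embedded selection + self-organising classification.

    Per fold: fit the CWINCA selector on the training partition only, fit
    the tkNN classifier (inner stratified fivefold tuning) on the selected
    training columns, predict the held-out fold once, and accumulate the
    confusion matrix over folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    plan = make_folds(y, mode=mode, k=folds, seed=seed, subjects=subjects)
    class_pos = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=np.int64)
    logs: list[FoldLog] = []
    for f, (train, test) in enumerate(plan.split()):
        selector = CWINCASelector(
            random_state=seed, **(selector_params or {})
        )
        selector.fit(X[train], y[train])
        clf = TkNNClassifier(random_state=seed, **(classifier_params or {}))
        clf.fit(selector.transform(X[train]), y[train])
        pred = clf.predict(selector.transform(X[test]))
        for yt, yp in zip(y[test], pred):
            confusion[class_pos[yt], class_pos[yp]] += 1
        logs.append(
            FoldLog(
                fold=f,
                train_indices=train,
                test_indices=test,
                selection_indices=train.copy(),
                selection=selector.selection_,
                best_parameter=clf.best_outcome_.parameter_id,
                test_accuracy=float(np.mean(pred == y[test])),
            )
        )
    report = compute_metrics(confusion, class_labels=list(classes))
    return report, logs


def audit_no_leakage(logs: list[FoldLog]) -> bool:
    """Assert the no-leakage property: test and selection indices disjoint."""
    for log in logs:
        overlap = np.intersect1d(log.test_indices, log.selection_indices)
        if overlap.size:
            raise AssertionError(
                f"fold {log.fold}: test samples {overlap.tolist()} "
                "entered selection/tuning"
            )
    return True
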