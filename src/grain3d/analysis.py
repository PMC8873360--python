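"""Trait statistics and the classification protocol.

Covers Z-score standardisation (population sd), Pearson correlation
matrices, the manual-vs-system error metrics (MAPE, RMSE and the
determination coefficient R^2 = 1 - sum((x-y)^2) / sum((x - ybar)^2) with
ybar the mean of the *system* values — implemented exactly as printed, which
differs from the textbook definition), and a six-method tenfold
cross-validation harness (CART, random forest, SVM, Gaussian naive Bayes,
BP neural network, XGBoost) with macro-averaged precision/recall/F1 and
feature-importance ranking for the tree methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "StandardizedMatrix",
    "ErrorMetrics",
    "ClassificationReport",
    "zscore",
    "pearson_matrix",
    "error_metrics",
    "crossval_classify",
    "feature_importance",
    "CLASSIFIER_METHODS",
]

CLASSIFIER_METHODS = ("cart", "rf", "svm", "nb", "bp", "xgboost")
_IMPORTANCE_METHODS = ("cart", "rf", "xgboost")


@dataclass
class StandardizedMatrix:
    """Column-standardised matrix with the means/sds used and the indices of
    zero-variance columns (output as all-zeros)."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    zero_variance_columns: List[int] = field(default_factory=list)


@dataclass
class ErrorMetrics:
    """Manual (x) vs system (y) agreement: MAPE in percent, RMSE in input
    units, and the determination coefficient. ``r2`` is NaN (and flagged)
    when its denominator sum((x - ybar)^2) vanishes."""

    mape_pct: float
    rmse: float
    r2: float
    n: int
    r2_defined: bool = True


@dataclass
class ClassificationReport:
    """Tenfold-CV result for one method: per-fold accuracies (percent),
    macro-averaged precision (percent) / recall / F1, and, for tree methods,
    normalised feature importances."""

    method: str
    fold_accuracies: np.ndarray
    precision_pct: float
    recall: float
    f1: float
    importance: Optional[List[Tuple[str, float]]] = None
    seed: int = 0
    n_samples: int = 0

    @property
    def accuracy_pct(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "accuracy_pct": self.accuracy_pct,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "precision_pct": self.precision_pct,
            "recall": self.recall,
            "f1": self.f1,
            "importance": None if self.importance is None
            else [[t, float(wt)] for t, wt in self.importance],
            "seed": self.seed,
            "n_samples": self.n_samples,
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def zscore(matrix) -> StandardizedMatrix:
    """Column-wise Z-score standardisation X* = (X - mu) / sigma with the
    population standard deviation. Zero-sd columns come out as all zeros and
    are flagged."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardise")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd (ddof = 0)
    zero = np.flatnonzero(sd == 0)
    safe = np.where(sd == 0, 1.0, sd)
    values = (X - mu) / safe
    values[:, zero] = 0.0
    return StandardizedMatrix(values=values, column_means=mu, column_sds=sd,
                              zero_variance_columns=[int(i) for i in zero])


def pearson_matrix(matrix) -> np.ndarray:
    """Pearson correlation matrix of the columns: symmetric, unit diagonal,
    entries in [-1, 1]. Entries involving a zero-variance column are 0."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    bad = sd == 0
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def error_metrics(x_manual, y_system) -> ErrorMetrics:
    """MAPE, RMSE and determination coefficient of system values y against
    manual reference x.

    MAPE = (1/n) sum |x_i - y_i| / x_i * 100
    RMSE = sqrt(sum (x_i - y_i)^2 / n)
    R^2  = 1 - sum (x_i - y_i)^2 / sum (x_i - ybar)^2,  ybar = mean(y)
    """
    x = np.asarray(x_manual, dtype=float).reshape(-1)
    y = np.asarray(y_system, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 1:
        raise ValueError("need at least one measurement")
    if np.any(x == 0):
        raise ValueError("MAPE undefined: some manual values are zero")
    mape = float(np.mean(np.abs(x - y) / np.abs(x)) * 100.0)
    sq = (x - y) ** 2
    rmse = float(np.sqrt(sq.sum() / n))
    ybar = y.mean()
    denom = ((x - ybar) ** 2).sum()
    if denom == 0:
        return ErrorMetrics(mape_pct=mape, rmse=rmse, r2=float("nan"), n=n,
                            r2_defined=False)
    return ErrorMetrics(mape_pct=mape, rmse=rmse, r2=float(1.0 - sq.sum() / denom), n=n)


def _build_model(method: str, seed: int):
    if method == "cart":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(criterion="entropy", max_depth=4,
                                      splitter="random", random_state=seed)
    if method == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(max_depth=2, criterion="gini",
                                      n_estimators=24, random_state=seed)
    if method == "svm":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", C=6.0, random_state=seed)
    if method == "nb":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    if method == "bp":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(hidden_layer_sizes=(100, 50), max_iter=2000,
                             learning_rate_init=0.0003237, random_state=seed)
    if method == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=20, max_depth=5, learning_rate=0.3,
                             objective="binary:logistic", random_state=seed,
                             n_jobs=1, verbosity=0)
    raise ValueError(f"unknown method {method!r}; choose from {CLASSIFIER_METHODS}")


def crossval_classify(traits, labels, method: str, seed: int = 0,
                      stratify: bool = True,
                      feature_names: Optional[Sequence[str]] = None) -> ClassificationReport:
    """Tenfold cross-validation of one classifier on a trait matrix.

    The data are shuffled and split into 10 folds (stratified by class by
    default); each fold serves once as the test set while the other nine
    train. Reported accuracy is the mean of the fold accuracies;
    precision/recall/F1 are macro-averaged over classes and folds. Tree
    methods (cart, rf, xgboost) also carry fold-averaged feature importances
    normalised to sum 1. Deterministic given (data, method, seed).
    """
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.metrics import precision_score, recall_score, f1_score
    from sklearn.model_selection import KFold, StratifiedKFold
    from sklearn.preprocessing import LabelEncoder

    X = traits.values if isinstance(traits, StandardizedMatrix) else np.asarray(traits, dtype=float)
    y_raw = np.asarray(labels)
    if X.shape[0] != y_raw.shape[0]:
        raise ValueError("traits and labels must have the same length")
    if X.shape[0] < 20:
        raise ValueError("need at least 20 samples for tenfold CV")
    classes, counts = np.unique(y_raw, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 10:
        raise ValueError("every class needs at least 10 members for tenfold CV")
    enc = LabelEncoder()
    y = enc.fit_transform(y_raw)
    splitter = (StratifiedKFold if stratify else KFold)(
        n_splits=10, shuffle=True, random_state=seed
    )
    accs, precs, recs, f1s, imps = [], [], [], [], []
    for train, test in splitter.split(X, y):
        model = _build_model(method, seed)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X[train], y[train])
        pred = model.predict(X[test])
        accs.append(float(np.mean(pred == y[test]) * 100.0))
        precs.append(precision_score(y[test], pred, average="macro", zero_division=0))
        recs.append(recall_score(y[test], pred, average="macro", zero_division=0))
        f1s.append(f1_score(y[test], pred, average="macro", zero_division=0))
        if method in _IMPORTANCE_METHODS:
            imps.append(np.asarray(model.feature_importances_, dtype=float))
    importance = None
    if imps:
        mean_imp = np.mean(imps, axis=0)
        total = mean_imp.sum()
        if total > 0:
            mean_imp = mean_imp / total
        names = list(feature_names) if feature_names is not None \
            else [f"feature_{i}" for i in range(X.shape[1])]
        order = np.argsort(mean_imp)[::-1]
        importance = [(names[i], float(mean_imp[i])) for i in order]
    return ClassificationReport(
        method=method,
        fold_accuracies=np.asarray(accs),
        precision_pct=float(np.mean(precs) * 100.0),
        recall=float(np.mean(recs)),
        f1=float(np.mean(f1s)),
        importance=importance,
        seed=seed,
        n_samples=X.shape[0],
    )


def feature_importance(report: ClassificationReport,
                       threshold: Optional[float] = None) -> List[Tuple[str, float]]:
    """Ranked (trait, weight) list from a tree-method report.

    Weights are non-negative, sorted descending and sum to 1. Passing
    ``threshold`` (e.g. 0.04) filters the report to the traits above that
    weight, the usual way dominant traits are tabulated."""
    if report.importance is None:
        raise ValueError(
            f"method {report.method!r} does not expose feature importances; "
            f"use one of {_IMPORTANCE_METHODS}"
        )
    if threshold is None:
        return list(report.importance)
    return [(t, w) for t, w in report.importance if w > threshold]
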