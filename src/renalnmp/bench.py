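"""Classifier benchmark: five families, kidney-grouped leave-one-out
validation, and a stratified holdout test.

Each leave-one-out fold holds out one kidney with all of its features, so no
kidney ever contributes to both sides of a fold; feature standardization is
refit inside every fold on the training side only.  Metrics are accuracy
plus macro-averaged precision and recall over the three function classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix, standardize

__all__ = ["ClassifierSpec", "Metrics", "BenchResult", "metrics",
           "loocv", "train_final_and_test", "run_bench", "FAMILIES"]

FAMILIES: tuple[str, ...] = ("svm", "rf", "knn", "log", "bay")

#: families whose distance/margin geometry needs feature scaling
SCALE_SENSITIVE: frozenset[str] = frozenset({"svm", "knn", "log"})


@dataclass
class ClassifierSpec:
    """One of the five benchmarked classifier families.

    Hyperparameters are fixed: linear-kernel one-vs-one SVM, 20-tree random
    forest, kNN with k=5 uniform Euclidean, logistic regression and Gaussian
    naive Bayes at library defaults.
    """

    family: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")

    def make(self, seed: int = 0):
        if self.family == "svm":
            return SVC(kernel="linear", decision_function_shape="ovo")
        if self.family == "rf":
            return RandomForestClassifier(n_estimators=20, random_state=seed)
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=5, weights="uniform",
                                        metric="euclidean")
        if self.family == "log":
            return LogisticRegression(max_iter=1000)
        return GaussianNB()


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float


def metrics(y_true: Sequence[int], y_pred: Sequence[int],
            classes: Sequence[int] = (1, 2, 3)) -> Metrics:
    """Accuracy plus macro precision/recall over the function classes.

    Classes absent from ``y_true`` have undefined recall and are excluded
    from both macro means (with a warning); a class that is never predicted
    contributes precision 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("label vectors must be equal-length and non-empty")
    present = [c for c in classes if np.any(y_true == c)]
    if len(present) < len(classes):
        warnings.warn(
            "classes absent from y_true excluded from macro averaging",
            stacklevel=2)
    precisions, recalls = [], []
    for c in present:
        tp = float(np.sum((y_pred == c) & (y_true == c)))
        fp = float(np.sum((y_pred == c) & (y_true != c)))
        fn = float(np.sum((y_pred != c) & (y_true == c)))
        precisions.append(tp / (tp + fp) if tp + fp > 0 else 0.0)
        recalls.append(tp / (tp + fn))
    return Metrics(
        accuracy=float(np.mean(y_true == y_pred)),
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
    )


def confusion(y_true, y_pred, classes: Sequence[int] = (1, 2, 3)) -> pd.DataFrame:
    """3x3 confusion matrix, rows = actual class, columns = predicted."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    mat = [[int(np.sum((y_true == a) & (y_pred == p))) for p in classes]
           for a in classes]
    idx = pd.Index(classes, name="actual")
    return pd.DataFrame(mat, index=idx, columns=pd.Index(classes, name="predicted"))


def _fit_predict(spec: ClassifierSpec, X_tr, y_tr, X_ev, seed: int,
                 scale: bool) -> np.ndarray:
    if scale and spec.family in SCALE_SENSITIVE:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X_tr, X_ev, _ = standardize(X_tr, X_ev)
    clf = spec.make(seed)
    clf.fit(X_tr.to_numpy(), y_tr.to_numpy())
    return clf.predict(X_ev.to_numpy())


def loocv(
    fm: FeatureMatrix,
    spec: ClassifierSpec,
    seed: int = 0,
    scale: bool = True,
) -> tuple[pd.Series, Metrics]:
    """Kidney-grouped leave-one-out validation on the training split.

    Returns the pooled out-of-fold predictions (indexed by kidney) and their
    metrics.  Folds whose training side loses a class entirely are still run
    (with a warning).
    """
    X, y = fm.subset("train")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training kidneys")
    preds = {}
    for kid in X.index:
        tr_mask = X.index != kid
        assert kid not in X.index[tr_mask], "validation kidney leaked into fold"
        y_tr = y[tr_mask]
        if len(np.unique(y_tr)) < len(np.unique(y)):
            warnings.warn(f"fold {kid}: a class vanished from the training side",
                          stacklevel=2)
        pred = _fit_predict(spec, X.loc[tr_mask], y_tr, X.loc[[kid]],
                            seed, scale)
        preds[kid] = int(pred[0])
    pred_series = pd.Series(preds, name="predicted").loc[X.index]
    return pred_series, metrics(y.to_numpy(), pred_series.to_numpy())


def train_final_and_test(
    fm: FeatureMatrix,
    spec: ClassifierSpec,
    seed: int = 0,
    scale: bool = True,
) -> tuple[pd.Series, Metrics, pd.DataFrame]:
    """Retrain on all training kidneys and score the holdout test kidneys."""
    X_tr, y_tr = fm.subset("train")
    X_te, y_te = fm.subset("test")
    if X_te.shape[0] == 0:
        raise ValueError("no test kidneys in this feature matrix")
    if list(X_tr.columns) != list(X_te.columns):
        raise ValueError("feature tags differ between train and test")
    if set(X_tr.index) & set(X_te.index):
        raise ValueError("train and test kidneys overlap")
    pred = _fit_predict(spec, X_tr, y_tr, X_te, seed, scale)
    pred_series = pd.Series(pred, index=X_te.index, name="predicted")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = metrics(y_te.to_numpy(), pred)
    return pred_series, m, confusion(y_te.to_numpy(), pred)


@dataclass
class BenchResult:
    """Full classifier x variant grid of validation and test results."""

    summary: pd.DataFrame           # rows: (variant, classifier) metrics
    per_kidney: pd.DataFrame        # id, actual, split, one column per cell
    confusions: dict[tuple[str, str], dict[str, pd.DataFrame]]
    best: list[tuple[str, str]] = field(default_factory=list)

    def metrics_for(self, variant: str, family: str) -> pd.Series:
        return self.summary.loc[(variant, family)]


def run_bench(
    variants: dict[str, FeatureMatrix],
    seed: int = 0,
    classifiers: Sequence[str] = FAMILIES,
    scale: bool = True,
) -> BenchResult:
    """Run every classifier on every feature variant.

    Per-cell failures are recorded as NaN metrics instead of aborting the
    grid.  ``best`` lists the (variant, classifier) cells tied for the top
    validation accuracy.
    """
    rows = []
    confusions: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
    any_fm = next(iter(variants.values()))
    per_kidney = pd.DataFrame({
        "actual": any_fm.y, "split": any_fm.split})

    for vname, fm in variants.items():
        for fam in classifiers:
            spec = ClassifierSpec(fam)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    val_pred, val_m = loocv(fm, spec, seed, scale)
                    te_pred, te_m, conf = train_final_and_test(
                        fm, spec, seed, scale)
                rows.append({
                    "variant": vname, "classifier": fam,
                    "val_accuracy": val_m.accuracy,
                    "val_precision": val_m.precision,
                    "val_recall": val_m.recall,
                    "test_accuracy": te_m.accuracy,
                    "test_precision": te_m.precision,
                    "test_recall": te_m.recall,
                })
                col = pd.concat([val_pred, te_pred])
                per_kidney[f"{vname}:{fam}"] = col
                confusions[(vname, fam)] = {
                    "validation": confusion(
                        fm.subset("train")[1].to_numpy(), val_pred.to_numpy()),
                    "test": conf,
                }
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"bench cell ({vname}, {fam}) failed: {exc}",
                              stacklevel=2)
                rows.append({"variant": vname, "classifier": fam,
                             **{k: np.nan for k in (
                                 "val_accuracy", "val_precision", "val_recall",
                                 "test_accuracy", "test_precision",
                                 "test_recall")}})
    summary = pd.DataFrame(rows).set_index(["variant", "classifier"])
    best_acc = summary["val_accuracy"].max()
    best = [idx for idx, v in summary["val_accuracy"].items()
            if np.isfinite(v) and v >= best_acc - 1e-12]
    return BenchResult(summary=summary, per_kidney=per_kidney,
                       confusions=confusions, best=best)
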