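"""Random-forest habitat classification with leave-one-out cross-validation.

Hyperparameters are selected per training fold by out-of-bag score over a
grid of forest sizes (100-2000 trees, step 100) and maximum depths
(unbounded, 10-110, step 10); depth 0 encodes unbounded.  Metrics cover
per-class and overall accuracy/precision/recall/F1, one-vs-rest AUC per
class (rank-based, midrank ties), and the confusion matrix.  Subject-level
decisions aggregate per-region predictions by majority vote with a 50%
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.utils.validation import check_X_y


@dataclass(frozen=True)
class HyperparameterGrid:
    """Forest-size / depth grid; depth 0 encodes an unbounded tree."""

    tree_counts: tuple[int, ...] = tuple(range(100, 2001, 100))
    max_depths: tuple[int, ...] = (0,) + tuple(range(10, 111, 10))

    def points(self):
        for n in self.tree_counts:
            for d in self.max_depths:
                yield n, d


def default_grid() -> HyperparameterGrid:
    return HyperparameterGrid()


def small_grid() -> HyperparameterGrid:
    """Reduced grid for desk-scale experiments."""
    return HyperparameterGrid(tree_counts=(100,), max_depths=(0,))


class OOBGridRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest whose (n_trees, max_depth) is chosen by OOB score.

    Attributes after ``fit``: ``best_params_`` (n_trees, max_depth with 0 =
    unbounded), ``oob_scores_`` per grid point, ``model_`` the refit forest,
    ``classes_``.
    """

    def __init__(self, grid: HyperparameterGrid | None = None, random_state: int = 0):
        self.grid = grid
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not np.all(np.isfinite(X)):
            bad = sorted(set(np.nonzero(~np.isfinite(X))[1].tolist()))
            raise ValueError(f"non-finite features in columns {bad}")
        grid = self.grid or small_grid()
        best = None
        self.oob_scores_ = {}
        for n_trees, depth in grid.points():
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                max_depth=None if depth == 0 else depth,
                oob_score=True,
                bootstrap=True,
                random_state=self.random_state,
                n_jobs=1,
            )
            rf.fit(X, y)
            score = rf.oob_score_
            self.oob_scores_[(n_trees, depth)] = float(score)
            if best is None or score > best[0]:
                best = (score, (n_trees, depth), rf)
        self.best_params_ = best[1]
        self.model_ = best[2]
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


def one_vs_rest_auc(scores: np.ndarray, labels: np.ndarray, classes=None) -> dict:
    """Rank-based (Mann-Whitney, midrank ties) one-vs-rest AUC per class.

    ``scores`` is (n_samples, n_classes) with columns ordered by ``classes``
    (default: sorted unique labels).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("AUC requires at least two classes")
    aucs = {}
    for ci, cls in enumerate(classes):
        pos = labels == cls
        n_pos = int(pos.sum())
        n_neg = int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError(f"class {cls!r} lacks positive or negative examples")
        ranks = rankdata(scores[:, ci])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        aucs[cls] = float(u / (n_pos * n_neg))
    return aucs


def majority_vote(predictions, threshold: float = 0.5):
    """Subject-level decision from per-region predicted labels.

    Returns ``(label, fraction, tie)``: the label whose vote fraction exceeds
    ``threshold``; otherwise the plurality label with ties broken by sorted
    label order, flagged with ``tie=True``.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("majority vote requires at least one prediction")
    values, counts = np.unique(np.asarray(predictions), return_counts=True)
    fractions = counts / counts.sum()
    order = np.lexsort((values.astype(str), -fractions))
    top = order[0]
    if fractions[top] > threshold:
        return values[top], float(fractions[top]), False
    tie = len(order) > 1 and np.isclose(fractions[order[0]], fractions[order[1]])
    return values[top], float(fractions[top]), bool(tie)


@dataclass
class ClassifierReport:
    classes: list
    confusion: np.ndarray  # rows = true, cols = predicted
    accuracy: float
    per_class_precision: dict
    per_class_recall: dict
    per_class_f1: dict
    per_class_auc: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    fold_predictions: pd.DataFrame = field(repr=False, default=None)
    selected_params: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": {str(k): v for k, v in self.per_class_precision.items()},
            "recall": {str(k): v for k, v in self.per_class_recall.items()},
            "f1": {str(k): v for k, v in self.per_class_f1.items()},
            "auc": {str(k): v for k, v in self.per_class_auc.items()},
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def loocv_evaluate(
    X,
    y,
    grid: HyperparameterGrid | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Leave-one-out evaluation: each sample is predicted by a forest whose
    hyperparameters were chosen by OOB score on the remaining samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        bad = sorted(set(np.nonzero(~np.isfinite(X))[1].tolist()))
        raise ValueError(f"non-finite features in columns {bad}")
    classes, counts = np.unique(y, return_counts=True)
    singletons = [str(c) for c, n in zip(classes, counts) if n < 2]
    if singletons:
        raise ValueError(f"classes with a single sample: {singletons}")
    n = len(y)
    preds = np.empty(n, dtype=y.dtype)
    probas = np.zeros((n, len(classes)))
    selected = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        model = OOBGridRandomForest(grid=grid, random_state=seed).fit(X[train], y[train])
        preds[i] = model.predict(X[i : i + 1])[0]
        p = model.predict_proba(X[i : i + 1])[0]
        # align fold class order to the global class order
        for ci, cls in enumerate(model.classes_):
            probas[i, np.searchsorted(classes, cls)] = p[ci]
        selected.append(model.best_params_)

    conf = confusion_matrix(y, preds, labels=classes)
    accuracy = float(np.trace(conf) / n)
    precision, recall, f1 = {}, {}, {}
    for ci, cls in enumerate(classes):
        tp = conf[ci, ci]
        p_den = conf[:, ci].sum()
        r_den = conf[ci, :].sum()
        prec = tp / p_den if p_den else 0.0
        rec = tp / r_den if r_den else 0.0
        precision[cls] = float(prec)
        recall[cls] = float(rec)
        f1[cls] = float(2 * prec * rec / (prec + rec)) if (prec + rec) else 0.0
    aucs = one_vs_rest_auc(probas, y, classes=classes)
    folds = pd.DataFrame({"true": y, "predicted": preds})
    for ci, cls in enumerate(classes):
        folds[f"proba_{cls}"] = probas[:, ci]
    return ClassifierReport(
        classes=list(classes),
        confusion=conf,
        accuracy=accuracy,
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        per_class_auc=aucs,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        fold_predictions=folds,
        selected_params=selected,
    )
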