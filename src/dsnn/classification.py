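"""Classification-based validation of imputation.

Normal-vs-cancer classification is run on three versions of the same data —
the fully observed original, the incomplete (zero-filled) matrix, and the
imputed matrix — at a grid of sampling ratios.  Features are reduced by PCA,
chi-square scoring, or mutual information (the count selected by grid search
on training folds only), classification uses KNN (k = 3) and a linear SVM,
and mean accuracy / support-weighted F1 over repeated stratified 5-fold
cross-validation are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import (
    SelectKBest,
    chi2,
    mutual_info_classif,
)
from sklearn.metrics import make_scorer
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_validate
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .evaluation import random_mask
from .io import ExpressionMatrix
from .pipeline import DSNNConfig, dsnn_impute

__all__ = [
    "ClassificationResult",
    "accuracy",
    "weighted_f1",
    "run_classification_experiment",
]

logger = logging.getLogger(__name__)

ARMS = ("observed", "recovered", "original")
FEATURE_METHODS = ("pca", "chi_square", "mutual_info")
CLASSIFIERS = ("knn3", "linear_svm")

#: grid-search ranges; clipped to the data dimensions at run time
FEATURE_COUNT_GRID = (10, 50, 100, 500, 1000)
PCA_COMPONENT_GRID = (5, 10, 20, 50)


@dataclass(frozen=True)
class ClassificationResult:
    sampling_ratio: float
    matrix_arm: str
    feature_method: str
    classifier: str
    accuracy: float
    weighted_f1: float


def _check_labels(truth, predicted) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if truth.size == 0:
        raise ValueError("label vectors must be non-empty")
    return truth, predicted


def accuracy(truth, predicted) -> float:
    """Fraction of samples whose predicted label matches the truth."""
    truth, predicted = _check_labels(truth, predicted)
    return float(np.mean(truth == predicted))


def weighted_f1(truth, predicted) -> float:
    """Support-weighted mean of per-class F1 scores.

    Per class: F1 = 2 * precision * recall / (precision + recall), taken as 0
    when precision and recall are both 0; weights are the class frequencies
    in the truth vector (accounts for label imbalance).
    """
    truth, predicted = _check_labels(truth, predicted)
    classes, supports = np.unique(truth, return_counts=True)
    total = truth.size
    score = 0.0
    for cls, support in zip(classes, supports):
        tp = np.sum((predicted == cls) & (truth == cls))
        fp = np.sum((predicted == cls) & (truth != cls))
        fn = np.sum((predicted != cls) & (truth == cls))
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        score += (support / total) * f1
    return float(score)


class MinShift(BaseEstimator, TransformerMixin):
    """Shift every feature by its (training) minimum so chi-square scoring
    receives non-negative inputs even on imputed matrices."""

    def fit(self, X, y=None):
        self.mins_ = np.min(X, axis=0)
        return self

    def transform(self, X):
        return np.maximum(X - self.mins_, 0.0)


def _grid(values, upper: int) -> list[int]:
    out = sorted({v for v in values if v <= upper})
    return out or [upper]


def _make_estimator(
    feature_method: str, classifier: str, n_features: int, n_train: int, seed: int
):
    """Pipeline of feature reduction + classifier wrapped in a grid search
    over the reduction size, fitted on training folds only."""
    if classifier == "knn3":
        clf = KNeighborsClassifier(n_neighbors=3)
    elif classifier == "linear_svm":
        clf = LinearSVC(dual="auto", max_iter=5000)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    if feature_method == "pca":
        upper = max(min(n_features, n_train - (n_train // 3) - 1), 1)
        steps = [("scale", StandardScaler()), ("reduce", PCA(random_state=seed))]
        grid = {"reduce__n_components": _grid(PCA_COMPONENT_GRID, upper)}
    elif feature_method == "chi_square":
        steps = [("shift", MinShift()), ("reduce", SelectKBest(chi2))]
        grid = {"reduce__k": _grid(FEATURE_COUNT_GRID, n_features)}
    elif feature_method == "mutual_info":
        mi = lambda X, y: mutual_info_classif(X, y, random_state=seed)  # noqa: E731
        steps = [("reduce", SelectKBest(mi))]
        grid = {"reduce__k": _grid(FEATURE_COUNT_GRID, n_features)}
    else:
        raise ValueError(f"unknown feature method {feature_method!r}")

    if classifier == "linear_svm" and feature_method != "pca":
        # raw intensities are poorly scaled for the SVM margin problem
        steps = steps + [("post_scale", StandardScaler())]
    pipe = Pipeline(steps + [("clf", clf)])
    sole = all(len(v) == 1 for v in grid.values())
    if sole:
        pipe.set_params(**{k: v[0] for k, v in grid.items()})
        return pipe
    return GridSearchCV(
        pipe,
        grid,
        cv=StratifiedKFold(3, shuffle=True, random_state=seed),
        scoring="accuracy",
        n_jobs=1,
    )


def run_classification_experiment(
    X: ExpressionMatrix,
    labels,
    ratios=(0.1, 0.3, 0.5, 0.7, 0.9),
    arms=ARMS,
    cfg: DSNNConfig | None = None,
    n_repeats: int = 20,
    feature_methods=FEATURE_METHODS,
    classifiers=CLASSIFIERS,
) -> pd.DataFrame:
    """Run the full protocol and return one row per
    ratio × arm × feature method × classifier with mean accuracy and mean
    weighted F1 over ``n_repeats`` shuffles of stratified 5-fold CV."""
    cfg = cfg or DSNNConfig()
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ValueError("labels must align with the rows (samples) of X")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("two-class labels required")
    if counts.min() < 5:
        raise ValueError("need at least 5 samples per class for 5-fold CV")
    for arm in arms:
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")

    m, n = X.shape
    seq = np.random.SeedSequence(cfg.seed)
    mask_rng = np.random.default_rng(seq.spawn(1)[0])
    acc_scorer = make_scorer(accuracy)
    f1_scorer = make_scorer(weighted_f1)

    rows = []
    for ratio in ratios:
        mask = random_mask(m, n, ratio, seed=mask_rng)
        arm_matrices = {}
        if "original" in arms:
            arm_matrices["original"] = X.values
        if "observed" in arms:
            arm_matrices["observed"] = np.where(mask.as_bool(), X.values, 0.0)
        if "recovered" in arms:
            arm_matrices["recovered"] = dsnn_impute(X, mask, cfg).values
        for arm in arms:
            data = arm_matrices[arm]
            for fm in feature_methods:
                for clf_name in classifiers:
                    accs, f1s = [], []
                    n_train = m - m // 5
                    for rep in range(n_repeats):
                        est = _make_estimator(
                            fm, clf_name, n, n_train, seed=cfg.seed + rep
                        )
                        cv = StratifiedKFold(
                            5, shuffle=True, random_state=cfg.seed + rep
                        )
                        res = cross_validate(
                            est,
                            data,
                            y,
                            cv=cv,
                            scoring={"acc": acc_scorer, "wf1": f1_scorer},
                            n_jobs=1,
                        )
                        accs.append(res["test_acc"].mean())
                        f1s.append(res["test_wf1"].mean())
                    rows.append(
                        ClassificationResult(
                            sampling_ratio=float(ratio),
                            matrix_arm=arm,
                            feature_method=fm,
                            classifier=clf_name,
                            accuracy=float(np.mean(accs)),
                            weighted_f1=float(np.mean(f1s)),
                        )
                    )
                    logger.info(
                        "ratio=%.2f arm=%s fm=%s clf=%s acc=%.3f wf1=%.3f",
                        ratio,
                        arm,
                        fm,
                        clf_name,
                        rows[-1].accuracy,
                        rows[-1].weighted_f1,
                    )
    return pd.DataFrame([r.__dict__ for r in rows])
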