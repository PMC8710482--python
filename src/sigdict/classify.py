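"""Per-channel seizure classification, AUC channel selection, and metrics.

Five classifier families are supported: linear discriminant analysis (LDA),
an RBF-kernel support vector machine, Gaussian naive Bayes, 1-nearest
neighbor, and a classification tree. Scale-sensitive families (SVM, kNN)
are wrapped with a standardizer fitted on training rows only. Each EEG
channel gets its own classifier; the channel with the highest test AUC is
selected for detection, and for patients whose best channel has sensitivity
or specificity below a threshold (default 80%), a 2-of-3 majority vote over
the three highest-AUC channels is tried and adopted only if it improves the
triggering metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .types_and_io import NON_SEIZURE, SEIZURE

CLASSIFIER_KINDS = ("lda", "svm", "nb", "knn", "tree")

__all__ = [
    "CLASSIFIER_KINDS",
    "ChannelResult",
    "Metrics",
    "make_classifier",
    "train_model",
    "score_channel",
    "select_best_channel",
    "vote_top3",
    "confusion_metrics",
    "kfold_cv",
]


@dataclass
class Metrics:
    """Sensitivity/specificity/accuracy in percent, per the usual
    confusion-count definitions (seizure is the positive class)."""

    sensitivity: float
    specificity: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


@dataclass
class ChannelResult:
    """Predictions, scores and summary measures for one channel."""

    channel: str
    predictions: np.ndarray  # boolean, True = seizure
    scores: np.ndarray       # continuous decision scores
    truth: np.ndarray        # boolean
    auc: float

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        """(TP, FN, TN, FP)."""
        tp = int(np.sum(self.predictions & self.truth))
        fn = int(np.sum(~self.predictions & self.truth))
        tn = int(np.sum(~self.predictions & ~self.truth))
        fp = int(np.sum(self.predictions & ~self.truth))
        return tp, fn, tn, fp

    @property
    def metrics(self) -> Metrics:
        return confusion_metrics(*self.confusion)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> Metrics:
    """Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
    (TP+TN)/total, each as a percentage."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("no seizure segments: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no non-seizure segments: specificity undefined")
    return Metrics(
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / (tp + fn + tn + fp),
    )


def make_classifier(kind: str, seed: int = 0, svm_c: float = 1.0):
    """Instantiate one of the five classifier families.

    Hyperparameters the method leaves open are fixed here: SVM uses an RBF
    kernel with gamma = 1/(dim * var) on standardized features and C = 1;
    kNN uses k = 1; the tree uses Gini impurity with no depth cap.
    """
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", gamma="scale", C=svm_c,
                        random_state=seed)),
        ])
    if kind == "nb":
        return GaussianNB()
    if kind == "knn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(n_neighbors=1)),
        ])
    if kind == "tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}; use {CLASSIFIER_KINDS}")


def _labels_to_bool(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray([lab == SEIZURE for lab in labels], dtype=bool)
    bad = [lab for lab in labels if lab not in (SEIZURE, NON_SEIZURE)]
    if bad:
        raise ValueError(f"unlabeled or unknown labels present: {bad[:3]}")
    return arr


def train_model(features: FeatureMatrix, kind: str, seed: int = 0):
    """Fit a classifier on a training feature matrix (both classes required)."""
    y = _labels_to_bool(features.labels)
    if y.all() or not y.any():
        raise ValueError("training set contains a single class")
    model = make_classifier(kind, seed=seed)
    model.fit(features.X, y)
    return model


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores: decision_function, else P(seizure), else labels."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X)[:, 1], dtype=float)
    return np.asarray(model.predict(X), dtype=float)


def score_channel(model, test_features: FeatureMatrix, channel: str) -> ChannelResult:
    """Predict the test pool of one channel and compute its AUC.

    AUC is the rank statistic over the continuous scores (midrank tie
    convention). Raises if the test truth is single-class.
    """
    if test_features.n_rows == 0:
        raise ValueError("test feature matrix is empty")
    truth = _labels_to_bool(test_features.labels)
    if truth.all() or not truth.any():
        raise ValueError(f"channel {channel}: test truth is single-class, "
                         "AUC undefined")
    preds = np.asarray(model.predict(test_features.X), dtype=bool)
    scores = decision_scores(model, test_features.X)
    auc = float(roc_auc_score(truth, scores))
    return ChannelResult(channel=channel, predictions=preds, scores=scores,
                         truth=truth, auc=auc)


def select_best_channel(results: Sequence[ChannelResult]) -> ChannelResult:
    """Channel with the highest AUC; ties break toward montage order
    (= input order)."""
    if not results:
        raise ValueError("no channel results")
    best = results[0]
    for r in results[1:]:
        if r.auc > best.auc:
            best = r
    return best


def vote_top3(
    results: Sequence[ChannelResult],
    metrics_threshold: float = 80.0,
) -> tuple[Metrics, list[str], bool]:
    """Best-channel detection with an optional 2-of-3 majority-vote rescue.

    If the best channel's sensitivity and specificity both reach
    ``metrics_threshold``, its result stands. Otherwise the three channels
    with highest AUC vote per segment (>= 2 seizure votes -> seizure), and
    the vote is adopted only if it improves the metric that triggered it.

    Returns (metrics, channels used, whether voting was adopted).
    """
    best = select_best_channel(results)
    base = best.metrics
    trigger_sens = base.sensitivity < metrics_threshold
    trigger_spec = base.specificity < metrics_threshold
    if not (trigger_sens or trigger_spec):
        return base, [best.channel], False
    if len(results) < 3:
        import logging
        logging.getLogger("sigdict").warning(
            "fewer than 3 channels; majority vote unavailable")
        return base, [best.channel], False

    order = sorted(
        range(len(results)), key=lambda i: (-results[i].auc, i)
    )[:3]
    top3 = [results[i] for i in order]
    votes = np.sum([r.predictions for r in top3], axis=0)
    voted_preds = votes >= 2
    voted = ChannelResult(
        channel="+".join(r.channel for r in top3),
        predictions=voted_preds, scores=votes.astype(float),
        truth=best.truth, auc=best.auc,
    )
    vm = voted.metrics
    improved = (trigger_sens and vm.sensitivity > base.sensitivity) or (
        trigger_spec and vm.specificity > base.specificity
    )
    if improved:
        return vm, [r.channel for r in top3], True
    return base, [best.channel], False


def kfold_cv(
    features: FeatureMatrix, kind: str, k: int = 5, seed: int = 0
) -> Metrics:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Folds come from a seeded shuffle, so the result is reproducible given
    the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = _labels_to_bool(features.labels)
    n_min = min(int(y.sum()), int((~y).sum()))
    if n_min < k:
        raise ValueError(
            f"smallest class has {n_min} rows; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = fn = tn = fp = 0
    for tr, te in skf.split(features.X, y):
        model = make_classifier(kind, seed=seed)
        model.fit(features.X[tr], y[tr])
        pred = np.asarray(model.predict(features.X[te]), dtype=bool)
        truth = y[te]
        tp += int(np.sum(pred & truth))
        fn += int(np.sum(~pred & truth))
        tn += int(np.sum(~pred & ~truth))
        fp += int(np.sum(pred & ~truth))
    return confusion_metrics(tp, fn, tn, fp)


def kfold_cv_scores(
    features: FeatureMatrix, kind: str, k: int = 5, seed: int = 0
) -> dict:
    """Stratified k-fold CV returning pooled metrics and pooled-score AUC."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = _labels_to_bool(features.labels)
    n_min = min(int(y.sum()), int((~y).sum()))
    if n_min < k:
        raise ValueError(
            f"smallest class has {n_min} rows; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.zeros(len(y), dtype=bool)
    scores = np.zeros(len(y), dtype=float)
    for tr, te in skf.split(features.X, y):
        model = make_classifier(kind, seed=seed)
        model.fit(features.X[tr], y[tr])
        preds[te] = np.asarray(model.predict(features.X[te]), dtype=bool)
        scores[te] = decision_scores(model, features.X[te])
    tp = int(np.sum(preds & y))
    fn = int(np.sum(~preds & y))
    tn = int(np.sum(~preds & ~y))
    fp = int(np.sum(preds & ~y))
    return {
        "metrics": confusion_metrics(tp, fn, tn, fp),
        "auc": float(roc_auc_score(y, scores)),
    }
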