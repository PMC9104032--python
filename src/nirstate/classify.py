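"""Leakage-free z-scoring, linear SVM, 5-fold CV and online replay.

Normalisation statistics (per-feature mean and n−1 SD) are always fitted
on training data only and applied to both training and test sets; in
cross-validation they are re-fitted inside every training fold, so no
test information leaks into the decision rule.  The classifier is a
hard/soft-margin linear SVM; a decision score of exactly zero is broken
deterministically toward "relax".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "NormalizationStats",
    "TrainedModel",
    "CvResult",
    "SubjectResult",
    "fit_normalizer",
    "train_classifier",
    "crossvalidate",
    "replay_online",
]

RELAX = "relax"
NBACK = "nback"
DEFAULT_C = 1.0


@dataclass(frozen=True)
class NormalizationStats:
    mean: np.ndarray
    sd: np.ndarray  # n-1 denominator

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd


@dataclass
class TrainedModel:
    """Normaliser + linear decision rule, trained on one feature matrix."""

    stats: NormalizationStats
    svm: SVC
    column_names: list[str]

    def decision_scores(self, features: FeatureMatrix) -> np.ndarray:
        if features.column_names != self.column_names:
            raise ValueError("feature columns do not match the training matrix")
        return self.svm.decision_function(self.stats.apply(features.values))

    def predict(self, features: FeatureMatrix) -> list[str]:
        # decision_function > 0 maps to the lexicographically larger class
        # (relax, with labels {nback, relax}); score exactly 0 -> relax.
        scores = self.decision_scores(features)
        pos = self.svm.classes_[1]
        neg = self.svm.classes_[0]
        tie = RELAX if RELAX in self.svm.classes_ else pos
        return [pos if s > 0 else (neg if s < 0 else tie) for s in scores]


@dataclass
class CvResult:
    fold_accuracies: list[float]  # fractions in [0, 1]
    mean_accuracy: float  # percent
    pooled_accuracy: float  # percent, over all epochs
    per_epoch_predictions: list[tuple[int, str, str]]  # (fold, true, predicted)
    confusion: dict[tuple[str, str], int]  # (true, predicted) -> count
    fold_assignment: list[int]  # fold id per epoch


@dataclass(frozen=True)
class SubjectResult:
    subject_id: str
    session: str  # calibration | online
    accuracy: float  # percent

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 100.0:
            raise ValueError("accuracy must lie in [0, 100] percent")


def fit_normalizer(train: FeatureMatrix | np.ndarray) -> NormalizationStats:
    """Per-feature mean and sample SD (n−1) from training rows only."""
    values = train.values if isinstance(train, FeatureMatrix) else np.asarray(train)
    if values.shape[0] < 2:
        raise ValueError("need at least two training rows to estimate SDs")
    sd = values.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        names = (
            [train.column_names[i] for i in zero[:5]]
            if isinstance(train, FeatureMatrix)
            else [str(i) for i in zero[:5]]
        )
        raise ValueError(f"zero-variance feature column(s): {', '.join(names)}")
    return NormalizationStats(mean=values.mean(axis=0), sd=sd)


def train_classifier(
    train: FeatureMatrix,
    stats: NormalizationStats | None = None,
    C: float = DEFAULT_C,
) -> TrainedModel:
    """Fit the linear SVM on z-scored features; deterministic given (data, C)."""
    if len(set(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    if stats is None:
        stats = fit_normalizer(train)
    svm = SVC(kernel="linear", C=C)
    svm.fit(stats.apply(train.values), np.asarray(train.labels))
    return TrainedModel(stats=stats, svm=svm, column_names=list(train.column_names))


def _subset(features: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=features.values[idx],
        labels=[features.labels[i] for i in idx],
        column_names=list(features.column_names),
    )


def crossvalidate(
    features: FeatureMatrix,
    k: int = 5,
    C: float = DEFAULT_C,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold CV with fold-internal normalisation.

    Folds preserve class proportions (with ~20 epochs, unstratified
    splits can easily go single-class) and are reproducible from the
    seed.  Accuracy is reported both as the mean over folds (headline)
    and pooled over all test predictions.
    """
    n = features.n_epochs
    if k > n:
        raise ValueError(f"k={k} exceeds the number of epochs ({n})")
    labels = np.asarray(features.labels)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < k):
        raise ValueError(f"each class needs at least k={k} epochs for k folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.empty(n, dtype=int)
    fold_accuracies: list[float] = []
    per_epoch: list[tuple[int, str, str] | None] = [None] * n
    confusion: dict[tuple[str, str], int] = {}
    for fold, (train_idx, test_idx) in enumerate(skf.split(features.values, labels)):
        fold_assignment[test_idx] = fold
        model = train_classifier(_subset(features, train_idx), C=C)
        preds = model.predict(_subset(features, test_idx))
        correct = 0
        for i, pred in zip(test_idx, preds):
            true = features.labels[i]
            per_epoch[i] = (fold, true, pred)
            confusion[(true, pred)] = confusion.get((true, pred), 0) + 1
            correct += pred == true
        fold_accuracies.append(correct / len(test_idx))
    pooled = sum(c for (t, p), c in confusion.items() if t == p) / n
    return CvResult(
        fold_accuracies=fold_accuracies,
        mean_accuracy=100.0 * float(np.mean(fold_accuracies)),
        pooled_accuracy=100.0 * pooled,
        per_epoch_predictions=[p for p in per_epoch if p is not None],
        confusion=confusion,
        fold_assignment=fold_assignment.tolist(),
    )


def replay_online(
    calibration: FeatureMatrix,
    online: FeatureMatrix,
    C: float = DEFAULT_C,
) -> tuple[list[str], float, TrainedModel]:
    """Train once on the whole calibration session, stream the online epochs.

    Returns the per-epoch decision stream (the simulated feedback
    signal), the overall accuracy in percent against the online labels,
    and the fitted model.
    """
    model = train_classifier(calibration, C=C)
    preds = model.predict(online)
    acc = 100.0 * float(
        np.mean([p == t for p, t in zip(preds, online.labels)])
    )
    return preds, acc, model
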