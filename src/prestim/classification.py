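"""Classifiers, the random benchmark, and the repeated-CV harness.

Three classifiers are compared: LDA with a pseudo-inverse shared
covariance, a soft-margin RBF SVM with C = 1, and 1-nearest-neighbour with
Euclidean distance. A uniform random classifier (Pr{high} = Pr{low} = 0.5)
serves as the benchmark and is evaluated inside the same cross-validation
harness so its accuracy distribution has the same sampling structure as the
real classifiers.

The harness runs a stratified 10-fold cross-validation repeated 10 times.
Feature scoring and selection are recomputed on every training fold —
never on the full data — so the reported accuracies carry no selection
leakage. For time-resolved (dynamic) decoding the same harness runs
independently on each sliding-window feature set, giving per-classifier
accuracy sequences over window start times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix
from .selection import DEFAULT_THRESHOLD, biserial_r2_scores, select_by_cumulative_score

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "DynamicResult",
    "default_classifiers",
    "train_predict",
    "accuracy",
    "repeated_cv",
    "dynamic_repeated_cv",
]

KINDS = ("LDA", "SVM", "KNN", "RANDOM")


@dataclass
class ClassifierSpec:
    """One classifier configuration.

    Defaults follow the comparison design: LDA inverts the shared
    covariance by pseudo-inverse (SVD solver), the SVM is soft-margin RBF
    with C = 1 and the 'scale' bandwidth heuristic gamma = 1/(d * Var), and
    kNN uses k = 1 with Euclidean distance (ties broken by lowest training
    index). RANDOM predicts each test label uniformly at random.
    """

    kind: str
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    knn_k: int = 1

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    def build(self):
        if self.kind == "LDA":
            return LinearDiscriminantAnalysis(solver="svd")
        if self.kind == "SVM":
            return SVC(C=self.svm_C, kernel="rbf", gamma=self.svm_gamma)
        if self.kind == "KNN":
            return KNeighborsClassifier(n_neighbors=self.knn_k, metric="euclidean",
                                        algorithm="brute")
        return None  # RANDOM needs no model


def default_classifiers() -> list[ClassifierSpec]:
    """LDA, SVM, kNN and the random benchmark, in the canonical order."""
    return [ClassifierSpec(k) for k in KINDS]


@dataclass
class CVResult:
    """Repeated-CV accuracies: ``mean_accuracy`` is repeats x classifiers."""

    mean_accuracy: np.ndarray
    fold_accuracy: np.ndarray  # repeats x folds x classifiers
    classifier_kinds: list[str]
    n_folds: int
    seed: int
    threshold_frac: float
    selection_scope: str = "fold"


@dataclass
class DynamicResult:
    """Per-segment repeated-CV accuracies and (once computed) statistics.

    ``acc_sequences`` is classifiers x repeats x segments. The p-value and
    best-point fields are filled by the statistics stage.
    """

    acc_sequences: np.ndarray
    segment_times: np.ndarray
    classifier_kinds: list[str]
    seed: int
    p_corrected: np.ndarray | None = None
    best_points: dict = field(default_factory=dict)


def train_predict(spec: ClassifierSpec, train: FeatureMatrix, test: FeatureMatrix,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Fit on the training matrix and predict labels for the test matrix."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    if train.n_features != test.n_features:
        raise ValueError("train and test feature dimensions differ")
    if spec.kind == "RANDOM":
        if rng is None:
            rng = np.random.default_rng(0)
        return rng.integers(0, 2, size=test.n_instances)
    model = spec.build()
    model.fit(train.values, train.labels)
    return model.predict(test.values)


def accuracy(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Fraction of correct predictions."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have the same length")
    if predicted.size == 0:
        raise ValueError("empty prediction set")
    return float((predicted == actual).mean())


def _fit_predict_values(spec: ClassifierSpec, x_train, y_train, x_test,
                        rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "RANDOM":
        return rng.integers(0, 2, size=x_test.shape[0])
    model = spec.build()
    model.fit(x_train, y_train)
    return model.predict(x_test)


def repeated_cv(features: FeatureMatrix,
                specs: Sequence[ClassifierSpec] | None = None,
                n_folds: int = 10, n_repeats: int = 10,
                threshold_frac: float = DEFAULT_THRESHOLD,
                seed: int = 0,
                selection_scope: str = "fold") -> CVResult:
    """Repeated stratified k-fold CV with in-fold feature selection.

    For each repeat the instances are shuffled (seeded) into stratified
    folds. Within each fold, biserial r² scores and the cumulative-score
    selection are computed on the training portion only and applied to both
    portions before training every classifier. ``selection_scope='full'``
    instead selects once on the complete data — a deliberately leaky
    variant kept for regression-testing the harness, never for reporting.
    """
    specs = list(specs) if specs is not None else default_classifiers()
    if selection_scope not in ("fold", "full"):
        raise ValueError("selection_scope must be 'fold' or 'full'")
    y = features.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < n_folds:
        raise ValueError(
            f"need at least {n_folds} instances of each class for stratified "
            f"{n_folds}-fold CV"
        )
    rng = np.random.default_rng(seed)
    x = features.values

    full_selected = None
    if selection_scope == "full":
        full_selected = select_by_cumulative_score(
            biserial_r2_scores(x, y), threshold_frac)

    fold_acc = np.zeros((n_repeats, n_folds, len(specs)))
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for f, (tr, te) in enumerate(skf.split(x, y)):
            if selection_scope == "fold":
                sel = select_by_cumulative_score(
                    biserial_r2_scores(x[tr], y[tr]), threshold_frac)
            else:
                sel = full_selected
            x_tr, x_te = x[tr][:, sel], x[te][:, sel]
            for c, spec in enumerate(specs):
                pred = _fit_predict_values(spec, x_tr, y[tr], x_te, rng)
                fold_acc[r, f, c] = accuracy(pred, y[te])
    return CVResult(mean_accuracy=fold_acc.mean(axis=1), fold_accuracy=fold_acc,
                    classifier_kinds=[s.kind for s in specs], n_folds=n_folds,
                    seed=seed, threshold_frac=threshold_frac,
                    selection_scope=selection_scope)


def dynamic_repeated_cv(segment_features: Sequence[FeatureMatrix],
                        specs: Sequence[ClassifierSpec] | None = None,
                        n_folds: int = 10, n_repeats: int = 10,
                        threshold_frac: float = DEFAULT_THRESHOLD,
                        seed: int = 0,
                        segment_times: np.ndarray | None = None) -> DynamicResult:
    """Run :func:`repeated_cv` independently on every sliding-window segment.

    Returns per-classifier accuracy sequences (repeats x segments). Each
    segment gets its own derived seed so the whole run is reproducible from
    the one master seed.
    """
    specs = list(specs) if specs is not None else default_classifiers()
    if len(segment_features) == 0:
        raise ValueError("segment_features must be non-empty")
    n_instances = segment_features[0].n_instances
    for fm in segment_features:
        if fm.n_instances != n_instances:
            raise ValueError("all segments must describe the same instances")
    n_seg = len(segment_features)
    acc = np.zeros((len(specs), n_repeats, n_seg))
    seed_rng = np.random.default_rng(seed)
    for i, fm in enumerate(segment_features):
        res = repeated_cv(fm, specs, n_folds=n_folds, n_repeats=n_repeats,
                          threshold_frac=threshold_frac,
                          seed=int(seed_rng.integers(2**31 - 1)))
        acc[:, :, i] = res.mean_accuracy.T
    if segment_times is None:
        idx = np.array([fm.segment_index if fm.segment_index is not None else i
                        for i, fm in enumerate(segment_features)], dtype=float)
        segment_times = idx  # caller should supply real times in seconds
    return DynamicResult(acc_sequences=acc, segment_times=np.asarray(segment_times),
                         classifier_kinds=[s.kind for s in specs], seed=seed)
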