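"""RBF-kernel SVM training, grid search and stratified cross-validation.

The classifier is a multi-class support vector machine with a Gaussian
radial-basis kernel (libsvm engine via scikit-learn), the standard choice
for fixed-length sequence feature vectors. Hyperparameters C (penalty)
and gamma (kernel width) are tuned by exhaustive grid search over
log2-spaced values with stratified k-fold cross-validation; ties prefer
the smaller C, then the smaller gamma, so selection is deterministic.

Features are min-max scaled to [0, 1] with statistics taken from training
data only (scaling is essential for RBF kernels); the scaling and any
information-gain feature subset are frozen into the trained model and,
during cross-validation, re-fit inside every training fold so no test
information leaks into selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import ConfusionCounts
from .feature_selection import rank_features


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters of the RBF-SVM."""

    C: float = 1.0
    gamma: float = 1.0 / 239.0
    class_weight: str | None = None  # None or "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """The libsvm-guide grid: C in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2."""
    return 2.0 ** np.arange(-5, 16, 2), 2.0 ** np.arange(-15, 4, 2)


class _MinMaxScaler:
    """Min-max scaling to [0, 1] with frozen training statistics."""

    def __init__(self, matrix: np.ndarray):
        self.min_ = matrix.min(axis=0)
        span = matrix.max(axis=0) - self.min_
        span[span == 0] = 1.0  # constant features map to 0
        self.span_ = span

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.min_) / self.span_


@dataclass
class TrainedModel:
    """A fitted SVM plus the preprocessing frozen at training time."""

    svc: SVC = field(repr=False)
    scaler: _MinMaxScaler = field(repr=False)
    feature_indices: np.ndarray | None
    n_features_in: int
    config: SVMConfig
    feature_names: list[str] | None = None

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.svc.classes_)

    def _prepare(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != self.n_features_in:
            raise ValueError(
                f"expected input with {self.n_features_in} features, "
                f"got shape {matrix.shape}"
            )
        if self.feature_indices is not None:
            matrix = matrix[:, self.feature_indices]
        return self.scaler.transform(matrix)

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._prepare(matrix))

    def decision_scores(self, matrix: np.ndarray) -> dict[str, np.ndarray]:
        """One-vs-rest decision values per class, for ROC analysis."""
        values = self.svc.decision_function(self._prepare(matrix))
        if values.ndim == 1:  # binary: sklearn returns one column
            pos, neg = self.svc.classes_[1], self.svc.classes_[0]
            return {str(pos): values, str(neg): -values}
        return {str(c): values[:, i] for i, c in enumerate(self.svc.classes_)}

    def save(self, path: str | Path) -> None:
        import joblib

        joblib.dump(
            {
                "svc": self.svc,
                "scaler_min": self.scaler.min_,
                "scaler_span": self.scaler.span_,
                "feature_indices": self.feature_indices,
                "n_features_in": self.n_features_in,
                "config": self.config,
                "feature_names": self.feature_names,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        import joblib

        payload = joblib.load(path)
        scaler = _MinMaxScaler.__new__(_MinMaxScaler)
        scaler.min_ = payload["scaler_min"]
        scaler.span_ = payload["scaler_span"]
        return cls(
            svc=payload["svc"],
            scaler=scaler,
            feature_indices=payload["feature_indices"],
            n_features_in=payload["n_features_in"],
            config=payload["config"],
            feature_names=payload["feature_names"],
        )


def _make_svc(config: SVMConfig) -> SVC:
    return SVC(
        kernel="rbf",
        C=config.C,
        gamma=config.gamma,
        class_weight=config.class_weight,
        decision_function_shape="ovr",
        random_state=config.seed,
    )


def train(
    matrix: np.ndarray,
    labels: Sequence[str],
    config: SVMConfig,
    feature_indices: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Fit the RBF-SVM with training-set min-max scaling."""
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs at least 2 classes")
    n_features_in = matrix.shape[1]
    selected = matrix if feature_indices is None else matrix[:, feature_indices]
    scaler = _MinMaxScaler(selected)
    svc = _make_svc(config)
    svc.fit(scaler.transform(selected), labels)
    return TrainedModel(
        svc=svc,
        scaler=scaler,
        feature_indices=None if feature_indices is None else np.asarray(feature_indices),
        n_features_in=n_features_in,
        config=config,
        feature_names=feature_names,
    )


def _check_fold_feasibility(labels: np.ndarray, folds: int) -> None:
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold CV needs >= {folds} samples per class; "
            f"smallest class has {counts.min()}"
        )


def grid_search(
    matrix: np.ndarray,
    labels: Sequence[str],
    C_values: Sequence[float] | None = None,
    gamma_values: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    class_weight: str | None = None,
) -> SVMConfig:
    """Pick (C, gamma) maximizing mean stratified k-fold CV accuracy.

    Ties go to the smaller C, then the smaller gamma. Deterministic for a
    given seed.
    """
    if C_values is None or gamma_values is None:
        default_c, default_g = default_grid()
        C_values = default_c if C_values is None else C_values
        gamma_values = default_g if gamma_values is None else gamma_values
    C_values = sorted(float(c) for c in C_values)
    gamma_values = sorted(float(g) for g in gamma_values)
    if not C_values or not gamma_values:
        raise ValueError("grid must contain at least one C and one gamma value")

    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    _check_fold_feasibility(labels, folds)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(matrix, labels))

    best: tuple[float, SVMConfig] | None = None
    for c in C_values:
        for g in gamma_values:
            config = SVMConfig(C=c, gamma=g, class_weight=class_weight, seed=seed)
            correct = 0
            for train_idx, test_idx in splits:
                model = train(matrix[train_idx], labels[train_idx], config)
                correct += int(
                    (model.predict(matrix[test_idx]) == labels[test_idx]).sum()
                )
            acc = correct / len(labels)
            if best is None or acc > best[0]:
                best = (acc, config)
    assert best is not None
    return best[1]


@dataclass
class CVResult:
    """Aggregated outcome of a stratified k-fold cross-validation."""

    confusion: ConfusionCounts
    fold_confusions: list[ConfusionCounts] = field(repr=False)
    fold_assignment: np.ndarray = field(repr=False)  # fold index per sample
    decision_scores: dict[str, np.ndarray] = field(repr=False)
    truth: np.ndarray = field(repr=False)
    selected_indices: list[np.ndarray] = field(repr=False)

    @property
    def mean_accuracy(self) -> float:
        return self.confusion.overall_accuracy()


def cross_validate(
    matrix: np.ndarray,
    labels: Sequence[str],
    config: SVMConfig,
    folds: int = 10,
    seed: int = 0,
    top_k: int | None = None,
    bins: int = 10,
) -> CVResult:
    """Stratified k-fold CV with in-fold scaling and feature re-ranking.

    When ``top_k`` is given, information-gain ranking is recomputed on each
    training fold and the fold's own top-k subset applied to its test
    split, so feature selection never sees test labels. Each sample is
    tested exactly once; the aggregated confusion matrix is the sum over
    folds.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    _check_fold_feasibility(labels, folds)
    classes = tuple(np.unique(labels))
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    fold_assignment = np.full(len(labels), -1, dtype=int)
    fold_confusions: list[ConfusionCounts] = []
    selected: list[np.ndarray] = []
    scores = {str(c): np.zeros(len(labels)) for c in classes}

    for fold_idx, (train_idx, test_idx) in enumerate(splitter.split(matrix, labels)):
        fold_assignment[test_idx] = fold_idx
        indices = None
        if top_k is not None:
            ranked = rank_features(matrix[train_idx], labels[train_idx], bins=bins)
            indices = ranked.subset(min(top_k, matrix.shape[1]))
        model = train(matrix[train_idx], labels[train_idx], config, indices)
        predictions = model.predict(matrix[test_idx])
        fold_confusions.append(
            ConfusionCounts.from_predictions(labels[test_idx], predictions, classes)
        )
        for cls_name, values in model.decision_scores(matrix[test_idx]).items():
            scores[cls_name][test_idx] = values
        selected.append(
            np.arange(matrix.shape[1]) if indices is None else indices
        )

    total = fold_confusions[0]
    for fc in fold_confusions[1:]:
        total = total + fc
    return CVResult(
        confusion=total,
        fold_confusions=fold_confusions,
        fold_assignment=fold_assignment,
        decision_scores=scores,
        truth=labels.copy(),
        selected_indices=selected,
    )
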