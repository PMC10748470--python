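"""Binary singing/background classification over clip feature vectors.

Evaluation mirrors the original protocol: a stratified 75/25
train/validation split, stratified k-fold cross-validation (k = 10) with a
pooled out-of-fold confusion matrix, accuracy with an exact
(Clopper-Pearson) binomial confidence interval, and Cohen's kappa.  The
default learner is a random forest (500 trees); CART and k-nearest-
neighbors are available through the learner switch for comparison runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LearnerConfig",
    "ClassifierModel",
    "EvalReport",
    "split_train_validation",
    "fit",
    "predict",
    "cross_validate",
    "cohens_kappa",
    "accuracy_ci",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class LearnerConfig:
    learner: str = "random_forest"  # "random_forest" | "cart" | "knn"
    n_trees: int = 500
    n_neighbors: int = 5
    seed: int = 0

    def make_estimator(self):
        if self.learner == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.seed
            )
        if self.learner == "cart":
            return DecisionTreeClassifier(random_state=self.seed)
        if self.learner == "knn":
            return KNeighborsClassifier(n_neighbors=self.n_neighbors)
        raise ValueError(f"unknown learner {self.learner!r}")


@dataclass
class ClassifierModel:
    """A fitted learner bound to the feature names it was trained on."""

    estimator: object
    feature_names: list[str]
    config: LearnerConfig


@dataclass
class EvalReport:
    """Confusion matrix with the derived agreement statistics.

    ``confusion[i, j]`` counts true class ``i`` predicted as class ``j``
    (classes ordered background=0, singing=1).  Accuracy and kappa are
    always recomputed from the stored matrix, so they cannot disagree
    with it.
    """

    confusion: np.ndarray
    ci_level: float = 0.95
    per_fold_accuracy: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        if self.confusion.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.n)

    @property
    def kappa(self) -> float:
        return cohens_kappa(self.confusion)

    @property
    def accuracy_ci(self) -> tuple[float, float]:
        return accuracy_ci(self.confusion, level=self.ci_level)

    def to_dict(self) -> dict:
        lo, hi = self.accuracy_ci
        return {
            "confusion": self.confusion.tolist(),
            "n": self.n,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "ci_level": self.ci_level,
            "accuracy_ci": [lo, hi],
            "per_fold_accuracy": self.per_fold_accuracy,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# --------------------------------------------------------------------------- #
# splitting / fitting
# --------------------------------------------------------------------------- #


def _check_two_classes(y: np.ndarray) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")


def split_train_validation(
    X: pd.DataFrame,
    y: np.ndarray,
    fraction: float = 0.75,
    seed: int | None = 0,
    stratify: bool = True,
):
    """Stratified train/validation split (default 75/25)."""
    y = np.asarray(y)
    _check_two_classes(y)
    if fraction >= 1.0:
        warnings.warn("fraction >= 1: validation set is empty", stacklevel=2)
        return (X, y), (X.iloc[:0], y[:0])
    X_tr, X_va, y_tr, y_va = train_test_split(
        X,
        y,
        train_size=fraction,
        random_state=seed,
        stratify=y if stratify else None,
        shuffle=True,
    )
    return (X_tr, y_tr), (X_va, y_va)


def fit(
    X: pd.DataFrame, y: np.ndarray, config: LearnerConfig | None = None
) -> ClassifierModel:
    """Fit the configured learner; deterministic given ``config.seed``."""
    config = config or LearnerConfig()
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    est = config.make_estimator()
    est.fit(np.asarray(X, dtype=float), y)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    return ClassifierModel(estimator=est, feature_names=names, config=config)


def predict(model: ClassifierModel, X: pd.DataFrame) -> np.ndarray:
    """Predict 0/1 labels; an exact 0.5 ensemble vote counts as singing."""
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != model.feature_names:
            raise ValueError(
                f"feature names {list(X.columns)} do not match the model's "
                f"training features {model.feature_names}"
            )
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got shape {arr.shape}"
            )
    proba = model.estimator.predict_proba(arr)[:, 1]
    # ties favor sensitivity: a 50:50 vote is scored as singing
    return (proba >= 0.5).astype(int)


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    config: LearnerConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold CV; pooled confusion matrix of out-of-fold predictions."""
    config = config or LearnerConfig(seed=seed)
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y)
    if k > counts[counts > 0].min():
        raise ValueError(f"k={k} exceeds the size of the smallest class")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    Xa = np.asarray(X, dtype=float)
    confusion = np.zeros((2, 2), dtype=int)
    fold_acc: list[float] = []
    for train_idx, test_idx in skf.split(Xa, y):
        est = config.make_estimator()
        est.fit(Xa[train_idx], y[train_idx])
        pred = (est.predict_proba(Xa[test_idx])[:, 1] >= 0.5).astype(int)
        truth = y[test_idx]
        for t, p in zip(truth, pred):
            confusion[t, p] += 1
        fold_acc.append(float(np.mean(pred == truth)))
    return EvalReport(confusion=confusion, per_fold_accuracy=fold_acc)


# --------------------------------------------------------------------------- #
# agreement statistics
# --------------------------------------------------------------------------- #


def cohens_kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa, ``(p_o - p_e) / (1 - p_e)``, from a 2x2 count matrix.

    ``p_e`` is chance agreement from the marginals.  Degenerate marginals
    (``p_e = 1``) give kappa 1 for perfect agreement and raise otherwise.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (2, 2):
        raise ValueError("confusion matrix must be 2x2")
    n = cm.sum()
    if n <= 0:
        raise ValueError("confusion matrix must have a positive total count")
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: degenerate marginals with imperfect agreement")
    return float((p_o - p_e) / (1.0 - p_e))


def accuracy_ci(
    confusion: np.ndarray | tuple[int, int], level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI for accuracy.

    Accepts a 2x2 confusion matrix or a ``(n_correct, n_total)`` pair.
    """
    if isinstance(confusion, tuple):
        correct, n = confusion
    else:
        cm = np.asarray(confusion)
        correct, n = int(np.trace(cm)), int(cm.sum())
    if n <= 0:
        raise ValueError("need a positive number of trials")
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, correct, n - correct + 1) if correct > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, correct + 1, n - correct) if correct < n else 1.0
    return float(lo), float(hi)


# --------------------------------------------------------------------------- #
# persistence
# --------------------------------------------------------------------------- #


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Persist estimator (joblib) plus a JSON sidecar with version and config."""
    import joblib

    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": model.feature_names,
        "config": {
            "learner": model.config.learner,
            "n_trees": model.config.n_trees,
            "n_neighbors": model.config.n_neighbors,
            "seed": model.config.seed,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> ClassifierModel:
    import joblib

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return ClassifierModel(
        estimator=joblib.load(path),
        feature_names=sidecar["feature_names"],
        config=LearnerConfig(**sidecar["config"]),
    )
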