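"""Two-class glycemic-state classification from (HR, HRV).

Two tasks are supported on a cohort table:

- ``healthy_vs_dm`` — the recorded clinical diagnosis;
- ``normal_vs_hyper`` — the measured glucose class: normal is
  70-150 mg/dL inclusive, hyperglycemia is above 150 mg/dL (readings
  below 70 mg/dL are excluded from the two-class task).

Classifiers are a from-scratch k-nearest-neighbours vote over Euclidean
distances (k=5 default, with documented tie rules) and a soft-margin
RBF-kernel support vector machine (C=1, variance-scaled gamma; delegated
to scikit-learn). Features are z-scored with training-split statistics by
default: HR lives around 45-120 bpm and HRV around 0.002-0.2 s, so raw
Euclidean distances would be HR-only.

Evaluation uses a seeded stratified train/validation split (default 2/3
training) and reports the confusion matrix with the positive class on the
top row: counts [[TP, FN], [FP, TN]] plus the row-normalized percentage
matrix and per-class accuracies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import (
    DegenerateTrainingError,
    ParameterError,
    StratificationError,
)
from .io import validate_cohort

#: Glucose class boundaries, mg/dL: normal band is inclusive on both ends.
NORMAL_BAND = (70.0, 150.0)

FEATURE_COLUMNS = ("hr_bpm", "hrv_s")

#: Positive (top-row) class per task.
TASKS = {
    "healthy_vs_dm": ("diagnosis", "healthy", "dm"),
    "normal_vs_hyper": ("glucose_class", "normal", "hyperglycemia"),
}


@dataclass
class ClassifierConfig:
    """Settings shared by both classifiers and the evaluation harness."""

    method: str = "svm"
    k: int = 5
    c: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("knn", "svm"):
            raise ParameterError(f"method must be 'knn' or 'svm', got {self.method!r}")
        if self.k < 1 or self.k % 2 == 0:
            raise ParameterError("k must be odd and >= 1")
        if self.c <= 0:
            raise ParameterError("c must be positive")
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must lie in (0, 1)")


def assign_glucose_class(glucose: float) -> str:
    """Label a glucose reading: ``normal`` (70-150 mg/dL inclusive),
    ``hyperglycemia`` (>150), ``below_normal`` (<70)."""
    if not glucose > 0:
        raise ParameterError(f"glucose must be positive, got {glucose}")
    lo, hi = NORMAL_BAND
    if glucose < lo:
        return "below_normal"
    if glucose <= hi:
        return "normal"
    return "hyperglycemia"


def add_glucose_class(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the cohort table with a ``glucose_class`` column."""
    validate_cohort(table, for_analysis=True)
    out = table.copy()
    out["glucose_class"] = out["glucose_mg_dl"].map(assign_glucose_class)
    return out


def knn_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    queries: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """k-nearest-neighbours majority vote over Euclidean distances.

    Distance ties are broken by training-row order (stable sort); vote
    ties by the class with smaller mean distance among the k neighbours,
    then by lexicographic label order.
    """
    X = np.asarray(train_features, float)
    y = np.asarray(train_labels)
    Q = np.atleast_2d(np.asarray(queries, float))
    if X.ndim != 2 or Q.shape[1] != X.shape[1]:
        raise ParameterError("feature dimensions of train and query must match")
    if k > X.shape[0]:
        raise ParameterError(f"k={k} exceeds training size {X.shape[0]}")

    out = []
    for q in Q:
        d = np.sqrt(((X - q) ** 2).sum(axis=1))
        nn = np.argsort(d, kind="stable")[:k]
        votes = Counter(y[nn])
        top = max(votes.values())
        tied = sorted(lab for lab, v in votes.items() if v == top)
        if len(tied) > 1:
            mean_d = {lab: d[nn][y[nn] == lab].mean() for lab in tied}
            best = min(mean_d.values())
            tied = sorted(lab for lab in tied if mean_d[lab] == best)
        out.append(tied[0])
    return np.asarray(out)


def svm_fit_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    queries: np.ndarray,
    config: ClassifierConfig | None = None,
) -> np.ndarray:
    """Soft-margin RBF-kernel SVM: fit on the training set, label the
    queries. gamma='scale' is the 1/(d * Var(X)) rule."""
    cfg = config or ClassifierConfig()
    y = np.asarray(train_labels)
    if np.unique(y).size != 2:
        raise DegenerateTrainingError(
            f"SVM training needs exactly 2 classes, got {np.unique(y).size}"
        )
    model = SVC(kernel=cfg.kernel, C=cfg.c, gamma=cfg.gamma)
    model.fit(np.asarray(train_features, float), y)
    return model.predict(np.atleast_2d(np.asarray(queries, float)))


def stratified_split(
    table: pd.DataFrame,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    class_column: str = "glucose_class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded per-class proportional split into (train, validation).

    Per class, the training size is the nearest integer to
    ``train_fraction * n_class`` (exact halves round up, i.e. the
    remainder goes to training); the split is disjoint and exhaustive.
    """
    if not 0 < train_fraction < 1:
        raise ParameterError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    if class_column not in table.columns:
        raise ParameterError(f"missing class column {class_column!r}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for _, group in table.groupby(class_column, sort=True):
        if len(group) < 2:
            raise StratificationError(
                f"class with {len(group)} row(s) cannot be split"
            )
        perm = rng.permutation(len(group))
        n_train = int(np.floor(train_fraction * len(group) + 0.5))
        n_train = min(max(n_train, 1), len(group) - 1)
        pos = group.index.to_numpy()[perm]
        train_idx.extend(pos[:n_train])
        val_idx.extend(pos[n_train:])
    return table.loc[sorted(train_idx)], table.loc[sorted(val_idx)]


@dataclass
class ConfusionMatrix:
    """2x2 confusion matrix with the positive class on the top row."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive: str
    negative: str

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])

    @property
    def percentages(self) -> np.ndarray:
        """Row-normalized matrix in %, rows = true class."""
        c = self.counts.astype(float)
        return 100.0 * c / c.sum(axis=1, keepdims=True)

    @property
    def positive_accuracy(self) -> float:
        """Per-class accuracy of the positive class, %: tp/(tp+fn)."""
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def negative_accuracy(self) -> float:
        """Per-class accuracy of the negative class, %: tn/(tn+fp)."""
        return 100.0 * self.tn / (self.tn + self.fp)

    def to_dict(self) -> dict:
        return {
            "positive": self.positive,
            "negative": self.negative,
            "counts": self.counts.tolist(),
            "percentages": self.percentages.tolist(),
            "per_class_accuracy": {
                self.positive: self.positive_accuracy,
                self.negative: self.negative_accuracy,
            },
            "n_validation": self.n,
        }


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str, negative: str
) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == positive) & (y_pred == positive))),
        fn=int(np.sum((y_true == positive) & (y_pred != positive))),
        fp=int(np.sum((y_true != positive) & (y_pred == positive))),
        tn=int(np.sum((y_true != positive) & (y_pred != positive))),
        positive=positive,
        negative=negative,
    )


def evaluate_classifier(
    table: pd.DataFrame,
    task: str = "normal_vs_hyper",
    config: ClassifierConfig | None = None,
) -> ConfusionMatrix:
    """Train/validate one classifier on a cohort table.

    Rows outside the task's two classes (unknown diagnosis, below-normal
    glucose) are dropped; features are (HR, HRV), z-scored with
    training-split statistics when ``config.standardize``.
    """
    cfg = config or ClassifierConfig()
    if task not in TASKS:
        raise ParameterError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    column, positive, negative = TASKS[task]
    data = table if column in table.columns else add_glucose_class(table)
    data = data[data[column].isin([positive, negative])]
    if data[column].nunique() != 2:
        raise DegenerateTrainingError(f"task {task!r} needs both classes present")

    train, val = stratified_split(
        data, cfg.train_fraction, cfg.seed, class_column=column
    )
    X_tr = train.loc[:, FEATURE_COLUMNS].to_numpy(float)
    X_va = val.loc[:, FEATURE_COLUMNS].to_numpy(float)
    y_tr = train[column].to_numpy()
    y_va = val[column].to_numpy()

    if cfg.standardize:
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X_tr = (X_tr - mu) / sd
        X_va = (X_va - mu) / sd

    if cfg.method == "knn":
        y_hat = knn_predict(X_tr, y_tr, X_va, cfg.k)
    else:
        y_hat = svm_fit_predict(X_tr, y_tr, X_va, cfg)
    return confusion_from_labels(y_va, y_hat, positive, negative)
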