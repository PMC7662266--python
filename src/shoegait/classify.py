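"""Leave-one-participant-out gait classification and weighted metrics.

The modelling core is :class:`GaitClassificationModel`: built from a
feature table (segments x features with ``gait_class`` and
``participant_id`` columns), it runs leave-one-participant-out
cross-validation (LOOCV) — every fold holds out all segments of one
participant, standardizes and fits PCA on the training fold only,
trains one of four classifiers and returns a
:class:`GaitClassificationResults` carrying per-fold confusion matrices,
weighted metrics (mean ± SD across folds) and a ``summary()`` table.

Classifier hyperparameters default to: SVM (C=1, RBF kernel
k(x,x') = exp(−γ‖x−x'‖²) with γ = 1/(d·Var(X)) "scale", degree=3),
random forest (100 trees, Gini, min split 15, max depth 30, min leaf 1),
KNN (k=5, Euclidean, majority vote) and multinomial logistic regression
(logistic link φ(x) = 1/(1+e^{−f(x)}) with linear f).

Per-class precision is TP/(TP+FP) and recall TP/(TP+FN); the reported
precision/recall are weighted by true-class support, so weighted recall
on a single confusion matrix equals overall accuracy (trace/total).
Column error rates follow the predicted-class convention: for each
predicted column, (column sum − diagonal)/column sum as a percentage,
averaged unweighted over the five classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import META_COLUMNS
from .reduction import PCAModel, StandardizationModel
from .simulate import GAIT_CLASSES

CLASS_ORDER = GAIT_CLASSES  # (normal, unstable_left, unstable_right,
#                              supination/toe-out, pronation/toe-in)

ALGORITHMS = ("random_forest", "knn", "logistic_regression", "svm")


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice plus hyperparameters and a recorded seed."""

    algorithm: str
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid: {ALGORITHMS}"
            )

    @staticmethod
    def svm(rng_seed: int = 0, **params) -> "ClassifierSpec":
        base = dict(C=1.0, kernel="rbf", gamma="scale", degree=3)
        base.update(params)
        return ClassifierSpec("svm", base, rng_seed)

    @staticmethod
    def random_forest(rng_seed: int = 0, **params) -> "ClassifierSpec":
        base = dict(n_estimators=100, criterion="gini", min_samples_split=15,
                    max_depth=30, min_samples_leaf=1)
        base.update(params)
        return ClassifierSpec("random_forest", base, rng_seed)

    @staticmethod
    def knn(rng_seed: int = 0, **params) -> "ClassifierSpec":
        base = dict(n_neighbors=5, metric="euclidean")
        base.update(params)
        return ClassifierSpec("knn", base, rng_seed)

    @staticmethod
    def logistic_regression(rng_seed: int = 0, **params) -> "ClassifierSpec":
        base = dict(max_iter=2000)
        base.update(params)
        return ClassifierSpec("logistic_regression", base, rng_seed)

    def build(self):
        """Instantiate the scikit-learn estimator for this spec."""
        if self.algorithm == "svm":
            return SVC(random_state=self.rng_seed, **self.params)
        if self.algorithm == "random_forest":
            return RandomForestClassifier(random_state=self.rng_seed,
                                          **self.params)
        if self.algorithm == "knn":
            return KNeighborsClassifier(**self.params)
        return LogisticRegression(random_state=self.rng_seed, **self.params)


def classifier_specs(rng_seed: int = 0) -> dict[str, ClassifierSpec]:
    """The four benchmark classifiers with default hyperparameters."""
    return {
        "random_forest": ClassifierSpec.random_forest(rng_seed),
        "knn": ClassifierSpec.knn(rng_seed),
        "logistic_regression": ClassifierSpec.logistic_regression(rng_seed),
        "svm": ClassifierSpec.svm(rng_seed),
    }


@dataclass
class ConfusionMatrix:
    """True-by-predicted counts in a fixed class order."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         labels: tuple[str, ...] = CLASS_ORDER):
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(counts, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fp - self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label order mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy and support-weighted precision/recall, per class and overall."""

    accuracy: float
    weighted_precision: float
    weighted_recall: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    support: np.ndarray
    labels: tuple[str, ...]


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Weighted metrics of one confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn = cm.tp, cm.fp, cm.fn
    support = cm.counts.sum(axis=1)
    pred_tot = tp + fp
    if np.any((pred_tot == 0) & (support > 0)):
        warnings.warn(
            "class with no predictions: precision defined as 0", stacklevel=2
        )
    precision = np.where(pred_tot > 0, tp / np.maximum(pred_tot, 1), 0.0)
    recall = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
    w = support / cm.total
    return MetricsReport(
        accuracy=float(np.trace(cm.counts) / cm.total),
        weighted_precision=float(np.sum(w * precision)),
        weighted_recall=float(np.sum(w * recall)),
        per_class_precision=precision,
        per_class_recall=recall,
        support=support,
        labels=cm.labels,
    )


def column_error_rates(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per predicted-class error percentages and their unweighted mean.

    For each predicted column: (column sum − diagonal)/column sum × 100,
    0 for an empty column.
    """
    col = cm.counts.sum(axis=0)
    diag = np.diag(cm.counts)
    rates = np.where(col > 0, 100.0 * (col - diag) / np.maximum(col, 1), 0.0)
    return rates, float(rates.mean())


@dataclass(frozen=True)
class ReductionConfig:
    """Per-fold standardize+PCA settings for the LOOCV engine.

    ``n_pcs=None`` selects k per training fold by the cumulative
    explained-variance rule at ``variance_threshold``; an integer fixes
    k globally (component-sweep mode).
    """

    variance_threshold: float = 0.99
    n_pcs: int | None = None


def loso_folds(table: pd.DataFrame) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(participant_id, train_row_idx, test_row_idx) per participant."""
    pids = np.sort(table["participant_id"].unique())
    if pids.size < 2:
        raise ValueError("leave-one-participant-out needs >= 2 participants")
    all_idx = np.arange(len(table))
    pid_col = table["participant_id"].to_numpy()
    folds = []
    for pid in pids:
        test = all_idx[pid_col == pid]
        train = all_idx[pid_col != pid]
        folds.append((int(pid), train, test))
    return folds


def _split_xy(table: pd.DataFrame):
    feats = [c for c in table.columns if c not in META_COLUMNS]
    return table[feats].to_numpy(dtype=float), table["gait_class"].to_numpy()


def train_eval_fold(
    spec: ClassifierSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    reduction: ReductionConfig = ReductionConfig(),
) -> tuple[ConfusionMatrix, int]:
    """Standardize → PCA → fit → predict for one fold.

    Returns the test confusion matrix and the number of principal
    components used.  Deterministic given the spec's seed.
    """
    if len(train) == 0 or len(test) == 0:
        raise ValueError("fold sides must be nonempty")
    X_tr, y_tr = _split_xy(train)
    X_te, y_te = _split_xy(test)
    missing = set(CLASS_ORDER) - set(y_tr)
    if missing:
        warnings.warn(
            f"classes absent from training fold: {sorted(missing)}",
            stacklevel=2,
        )
    std = StandardizationModel().fit(X_tr)
    Z_tr = std.transform(X_tr)
    Z_te = std.transform(X_te)
    pca = PCAModel().fit(Z_tr)
    k = (reduction.n_pcs if reduction.n_pcs is not None
         else pca.n_components_for_variance(reduction.variance_threshold))
    clf = spec.build()
    clf.fit(pca.transform(Z_tr, k), y_tr)
    y_hat = clf.predict(pca.transform(Z_te, k))
    return ConfusionMatrix.from_predictions(y_te, y_hat), int(k)


class GaitClassificationResults:
    """LOOCV results: per-fold confusion matrices, metrics, summary."""

    def __init__(self, model: "GaitClassificationModel",
                 fold_matrices: dict[int, ConfusionMatrix],
                 fold_n_pcs: dict[int, int]):
        self.model = model
        self.fold_matrices = fold_matrices
        self.fold_n_pcs = fold_n_pcs
        self.fold_metrics = {
            pid: metrics(cm) for pid, cm in fold_matrices.items()
        }

    @property
    def participants(self) -> list[int]:
        return sorted(self.fold_matrices)

    @property
    def total_confusion(self) -> ConfusionMatrix:
        mats = list(self.fold_matrices.values())
        out = mats[0]
        for m in mats[1:]:
            out = out + m
        return out

    def per_fold(self, metric: str) -> np.ndarray:
        """Fold-wise metric values in participant order."""
        return np.array([getattr(self.fold_metrics[p], metric)
                         for p in self.participants])

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = self.per_fold(metric)
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return float(vals.mean()), sd

    @property
    def accuracy(self) -> float:
        return self.mean_sd("accuracy")[0]

    @property
    def weighted_precision(self) -> float:
        return self.mean_sd("weighted_precision")[0]

    @property
    def weighted_recall(self) -> float:
        return self.mean_sd("weighted_recall")[0]

    @property
    def mean_n_pcs(self) -> float:
        return float(np.mean(list(self.fold_n_pcs.values())))

    def to_dict(self) -> dict:
        """JSON-serializable per-fold report (matrices, metrics, n_pcs)."""
        acc_m, acc_s = self.mean_sd("accuracy")
        return {
            "classifier": self.model.spec.algorithm,
            "hyperparameters": self.model.spec.params,
            "rng_seed": self.model.spec.rng_seed,
            "n_features": self.model.n_features,
            "accuracy_mean": acc_m,
            "accuracy_sd": acc_s,
            "weighted_precision_mean": self.mean_sd("weighted_precision")[0],
            "weighted_recall_mean": self.mean_sd("weighted_recall")[0],
            "folds": {
                str(pid): {
                    "confusion_matrix": self.fold_matrices[pid].counts.tolist(),
                    "accuracy": self.fold_metrics[pid].accuracy,
                    "weighted_precision":
                        self.fold_metrics[pid].weighted_precision,
                    "weighted_recall": self.fold_metrics[pid].weighted_recall,
                    "n_pcs": self.fold_n_pcs[pid],
                } for pid in self.participants
            },
        }

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Leave-one-participant-out gait classification".center(64),
            "=" * 64,
            f"Classifier:        {spec.algorithm}",
            f"Hyperparameters:   {spec.params}",
            f"Participants:      {len(self.participants)}",
            f"Segments:          {len(self.model.table)}",
            f"Features:          {self.model.n_features}",
            f"Mean n PCs:        {self.mean_n_pcs:.1f}",
            "-" * 64,
        ]
        for name, attr in (("Accuracy", "accuracy"),
                           ("Weighted precision", "weighted_precision"),
                           ("Weighted recall", "weighted_recall")):
            m, s = self.mean_sd(attr)
            lines.append(f"{name:<20s} {100*m:6.2f} % +/- {100*s:5.2f}")
        lines.append("-" * 64)
        lines.append("Per-fold accuracy (%):")
        for p in self.participants:
            lines.append(
                f"  participant {p:>3d}: "
                f"{100*self.fold_metrics[p].accuracy:6.2f}"
                f"   (n_pcs={self.fold_n_pcs[p]})"
            )
        lines.append("=" * 64)
        return "\n".join(lines)


class GaitClassificationModel:
    """LOOCV evaluation of one classifier on a segment feature table.

    Parameters
    ----------
    table : DataFrame with feature columns plus ``gait_class`` and
        ``participant_id``.
    spec : classifier and hyperparameters (default: the benchmark SVM).
    reduction : per-fold standardization/PCA configuration.
    """

    def __init__(self, table: pd.DataFrame,
                 spec: ClassifierSpec | None = None,
                 reduction: ReductionConfig = ReductionConfig()):
        for col in META_COLUMNS:
            if col not in table.columns:
                raise ValueError(f"feature table lacks {col!r} column")
        self.table = table.reset_index(drop=True)
        self.spec = spec if spec is not None else ClassifierSpec.svm()
        self.reduction = reduction

    @property
    def n_features(self) -> int:
        return len([c for c in self.table.columns if c not in META_COLUMNS])

    def fit(self) -> GaitClassificationResults:
        """Run full leave-one-participant-out cross-validation."""
        fold_matrices: dict[int, ConfusionMatrix] = {}
        fold_n_pcs: dict[int, int] = {}
        for pid, train_idx, test_idx in loso_folds(self.table):
            cm, k = train_eval_fold(
                self.spec, self.table.iloc[train_idx],
                self.table.iloc[test_idx], self.reduction,
            )
            fold_matrices[pid] = cm
            fold_n_pcs[pid] = k
        return GaitClassificationResults(self, fold_matrices, fold_n_pcs)
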