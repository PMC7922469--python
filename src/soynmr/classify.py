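"""Discriminant-model evidence layer: LOO-CV, confusion metrics,
permutation tests and ROC.

A classification run is a regression of a 0/1 class code (case = 1) on the
scaled feature matrix; each sample's leave-one-out predicted value
("Ypredcv") is thresholded at 0.5 to assign a class. Model validity is
checked by permutation: the response is shuffled many times, the model
refit, and straight lines fit through the (|label correlation|, R2Y) and
(|label correlation|, Q2Y) point clouds, including the unpermuted model at
correlation 1; a model is accepted when the R2Y intercept is below 0.40 and
the Q2Y intercept below 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_curve

from .pls import FitStatistics, fit_statistics
from .preprocess import ColumnScaler

__all__ = [
    "ClassCoding",
    "one_vs_rest_codings",
    "CrossValResult",
    "ConfusionMetrics",
    "PermutationResult",
    "loo_cv",
    "classify_and_score",
    "permutation_test",
    "roc_auc",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    f = 10.0**decimals
    return math.floor(abs(x) * f + 0.5) / f * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ClassCoding:
    """Binary case/control coding of class labels.

    The case class is coded 1 and the control class(es) 0; a sample is
    predicted "case" iff its Ypredcv exceeds the threshold (a value exactly
    at the threshold — a probability-zero event — goes to control). For
    one-vs-rest designs on three classes this is the complement of the
    (0 1 1)/(1 0 1)/(1 1 0) dummy rows sometimes printed with 0 marking the
    case; after centring the two conventions give identical models.
    """

    class_names: tuple[str, ...]
    case_class: str
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.case_class not in self.class_names:
            raise ValueError(f"case class {self.case_class!r} not among classes")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def control_classes(self) -> tuple[str, ...]:
        return tuple(c for c in self.class_names if c != self.case_class)

    @property
    def name(self) -> str:
        return f"{self.case_class} vs. {'&'.join(self.control_classes)}"

    def encode(self, labels) -> np.ndarray:
        labels = np.asarray(labels)
        unknown = set(labels) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in coding classes")
        return (labels == self.case_class).astype(float)

    def decode(self, ypred: np.ndarray) -> np.ndarray:
        """Threshold predicted values into case/control labels."""
        control = "&".join(self.control_classes)
        return np.where(np.asarray(ypred) > self.threshold, self.case_class, control)


def one_vs_rest_codings(class_names) -> list[ClassCoding]:
    """One case-vs-rest coding per class, in the given class order."""
    names = tuple(class_names)
    if len(names) < 2:
        raise ValueError("need at least two classes")
    return [ClassCoding(class_names=names, case_class=c) for c in names]


@dataclass
class CrossValResult:
    """Per-sample leave-one-out class predictions."""

    ypredcv: pd.Series
    true_labels: pd.Series
    coding: ClassCoding

    @property
    def predicted_case(self) -> pd.Series:
        return self.ypredcv > self.coding.threshold

    @property
    def true_case(self) -> pd.Series:
        return pd.Series(
            self.coding.encode(self.true_labels.values).astype(bool),
            index=self.true_labels.index,
        )

    @property
    def misclassified_ids(self) -> list:
        wrong = self.predicted_case != self.true_case
        return list(self.ypredcv.index[wrong])


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and the derived percentage metrics."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return round_half_up(100.0 * self.tp / (self.tp + self.fn))

    @property
    def specificity(self) -> float:
        return round_half_up(100.0 * self.tn / (self.tn + self.fp))

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return round_half_up(100.0 * (self.tp + self.tn) / total)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def loo_cv(
    X,
    labels,
    coding: ClassCoding,
    model,
    *,
    scaling: str | None = "uv",
    variables=None,
    sample_ids=None,
) -> CrossValResult:
    """Leave-one-out cross-validated class prediction (Ypredcv).

    For each sample: remove it, refit the column scaling on the remainder,
    refit the model with its fixed component signature (and the fixed,
    full-data-selected variable subset, if any), and predict the held-out
    sample. Row-wise normalization is per-sample and assumed precomputed.

    Parameters
    ----------
    X : array-like or DataFrame, samples x variables
        Normalized (unscaled) feature matrix.
    labels : array-like
        Class labels matching ``coding``.
    model : estimator
        Configured, unfitted regressor; cloned per fold.
    scaling : {"uv", "pareto", "center", None}
        Column scaling refit within each fold.
    variables : sequence of int, optional
        Indices of retained variables (e.g. from a VIP cutoff).
    """
    if sample_ids is None:
        sample_ids = (
            list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(labels)))
        )
    Xa = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    y = coding.encode(labels)
    counts = pd.Series(labels).value_counts()
    if counts.min() < 3 or len(counts) < 2:
        raise ValueError("LOO-CV requires >= 3 samples in each of >= 2 classes")
    if variables is not None:
        Xa = Xa[:, np.asarray(variables, dtype=int)]
    n = len(y)
    ypred = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("a training fold lost an entire class")
        Xtr, xte = Xa[mask], Xa[i]
        if scaling is not None:
            s = ColumnScaler(method=scaling).fit(Xtr)
            Xtr, xte = s.transform(Xtr), s.transform(xte[None, :])[0]
        m = clone(model).fit(Xtr, y[mask])
        ypred[i] = float(np.asarray(m.predict(xte[None, :])).ravel()[0])
    return CrossValResult(
        ypredcv=pd.Series(ypred, index=sample_ids, name="ypredcv"),
        true_labels=pd.Series(labels, index=sample_ids, name="label"),
        coding=coding,
    )


def classify_and_score(result: CrossValResult) -> ConfusionMetrics:
    """Threshold Ypredcv at the coding threshold and tabulate the confusion."""
    pred = result.predicted_case.values
    true = result.true_case.values
    return ConfusionMetrics(
        tp=int(np.sum(pred & true)),
        tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


@dataclass
class PermutationResult:
    """Permutation-test point cloud and intercept diagnostics.

    ``records`` holds one row per model: |correlation| of the (permuted)
    response with the original, plus that model's R2Y and Q2Y. The
    unpermuted model is included as the point at correlation 1. Intercepts
    come from least-squares lines through all points.
    """

    records: pd.DataFrame
    r2y_intercept: float
    q2y_intercept: float
    original: FitStatistics
    r2y_bound: float = 0.40
    q2y_bound: float = 0.05

    @property
    def valid(self) -> bool:
        return (
            self.r2y_intercept < self.r2y_bound
            and self.q2y_intercept < self.q2y_bound
        )


def _mean_abs_correlation(Yp: np.ndarray, Y: np.ndarray) -> float:
    cs = []
    for j in range(Y.shape[1]):
        a, b = Yp[:, j], Y[:, j]
        sa, sb = a.std(), b.std()
        if sa < 1e-15 or sb < 1e-15:
            raise ValueError("degenerate response column (single class)")
        cs.append(abs(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(cs))


def permutation_test(
    X,
    Y,
    model,
    *,
    n_permutations: int = 100,
    seed: int = 0,
    cv: int = 7,
    scaler=None,
    stratify=None,
) -> PermutationResult:
    """Label-permutation validation with R2Y/Q2Y intercepts.

    Each permutation shuffles the rows of Y (and of the stratification
    labels, jointly), refits the model with the same component structure,
    and records the mean |Pearson correlation| with the original response
    together with R2Y and Q2Y. Straight lines of R2Y and Q2Y against the
    correlation, through all points including the unpermuted model at
    correlation 1, give the intercepts at correlation 0.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be >= 20")
    X = np.asarray(X, dtype=float)
    Y2 = np.asarray(Y, dtype=float)
    if Y2.ndim == 1:
        Y2 = Y2[:, None]
    labels = np.asarray(stratify) if stratify is not None else None
    kwargs = dict(cv=cv, scaler=scaler, random_state=seed % (2**31 - 1))
    orig = fit_statistics(model, X, Y2, stratify=labels, **kwargs)
    rows = [{"correlation": 1.0, "r2y": orig.r2y, "q2y": orig.q2y}]
    rng = np.random.default_rng(seed)
    for _ in range(n_permutations):
        perm = rng.permutation(len(Y2))
        Yp = Y2[perm]
        stats = fit_statistics(
            model, X, Yp, stratify=labels[perm] if labels is not None else None, **kwargs
        )
        rows.append(
            {
                "correlation": _mean_abs_correlation(Yp, Y2),
                "r2y": stats.r2y,
                "q2y": stats.q2y,
            }
        )
    records = pd.DataFrame(rows)
    x = records["correlation"].values
    r2_line = np.polyfit(x, records["r2y"].values, 1)
    q2_line = np.polyfit(x, records["q2y"].values, 1)
    return PermutationResult(
        records=records,
        r2y_intercept=float(r2_line[1]),
        q2y_intercept=float(q2_line[1]),
        original=orig,
    )


def roc_auc(scores, labels_or_cases) -> float:
    """Area under the ROC curve by the trapezoid rule.

    Equals the probability that a randomly chosen case outscores a randomly
    chosen control, ties counted one half.

    Parameters
    ----------
    scores : array-like
        Continuous classifier outputs (e.g. Ypredcv).
    labels_or_cases : array-like of bool/0-1
        True case indicators.
    """
    y = np.asarray(labels_or_cases).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = roc_curve(y, s)
    return float(np.trapezoid(tpr, fpr))
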