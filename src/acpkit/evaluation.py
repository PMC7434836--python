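"""Classifiers, stratified cross-validation and binary-classification metrics.

The evaluation protocol is *pooled* cross-validation: out-of-fold
predictions from every fold are concatenated into a single confusion
table before the metrics are computed once.  This is how single
Sn/Sp/Acc/MCC numbers are conventionally reported for peptide
classifiers on modest benchmarks; per-fold reports are also kept for
diagnostics.

Metrics, with TP/FP/TN/FN counted with the anticancer class positive:

    Sn  = TP / (TP + FN)                    (sensitivity, recall)
    Sp  = TN / (TN + FP)                    (specificity)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F   = 2·P·R / (P + R)   with P = TP/(TP+FP), R = Sn

Degenerate denominators follow the usual conventions (MCC = 0, F = 0,
P = 0) so that metric curves stay total over weak feature subsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, VotingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .encoders import FeatureMatrix
from .sequence_io import AcpkitError


class EvaluationError(AcpkitError):
    pass


# --------------------------------------------------------------------------
# Confusion counts and metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with the anticancer class (label 1) positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/TN/FN for binary labels (positive class = 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise EvaluationError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    for arr, which in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise EvaluationError(f"{which} must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


@dataclass
class MetricsReport:
    """Sn/Sp/Acc/MCC/F-score (plus precision/recall), recomputable from counts."""

    sn: float
    sp: float
    acc: float
    mcc: float
    f_score: float
    precision: float
    recall: float
    counts: ConfusionCounts
    fscore_mode: str = "positive"
    fold_reports: list | None = field(default=None, repr=False)
    fold_assignments: list | None = field(default=None, repr=False)

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {
            "Sn": self.sn * scale, "Sp": self.sp * scale,
            "Acc": self.acc * scale, "MCC": self.mcc * scale,
            "F-score": self.f_score * scale,
        }


def metrics(counts: ConfusionCounts, fscore: str = "positive") -> MetricsReport:
    """Compute the five-metric report from pooled confusion counts.

    ``fscore="positive"`` is the F1 of the anticancer class;
    ``"weighted"`` is the support-weighted average of the per-class F1s.
    """
    if counts.total == 0:
        raise EvaluationError("cannot compute metrics from all-zero counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = sn
    f_pos = (
        2 * precision * recall / (precision + recall)
        if precision + recall else 0.0
    )
    if fscore == "positive":
        f = f_pos
    elif fscore == "weighted":
        prec_neg = tn / (tn + fn) if tn + fn else 0.0
        f_neg = (
            2 * prec_neg * sp / (prec_neg + sp) if prec_neg + sp else 0.0
        )
        n_pos, n_neg = tp + fn, tn + fp
        f = (f_pos * n_pos + f_neg * n_neg) / counts.total
    else:
        raise EvaluationError(f"unknown fscore mode {fscore!r}")
    return MetricsReport(
        sn=sn, sp=sp, acc=acc, mcc=mcc, f_score=f,
        precision=precision, recall=recall, counts=counts, fscore_mode=fscore,
    )


# --------------------------------------------------------------------------
# Classifier specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """A fully serialisable classifier recipe.

    kind: ``"svm-rbf"`` (RBF-kernel SVM with cost ``c`` and kernel width
    ``g``, features standardised on the training folds), ``"random-forest"``
    (``n_estimators`` trees, default 100), or ``"vote-ensemble"`` (hard
    majority vote over ``members``, a plain stand-in ensemble).
    """

    kind: str
    c: float = 1.0
    g: float = 0.5
    n_estimators: int = 100
    members: tuple = ()

    def build(self, seed: int):
        if self.kind == "svm-rbf":
            return Pipeline([
                ("scale", StandardScaler()),
                ("svm", SVC(C=self.c, gamma=self.g, kernel="rbf",
                            random_state=seed)),
            ])
        if self.kind == "random-forest":
            return RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=seed
            )
        if self.kind == "vote-ensemble":
            members = self.members or (
                ClassifierSpec("random-forest"),
                ClassifierSpec("svm-rbf"),
            )
            return VotingClassifier(
                estimators=[
                    (f"m{i}_{m.kind}", m.build(seed + i))
                    for i, m in enumerate(members)
                ],
                voting="hard",
            )
        raise EvaluationError(f"unknown classifier kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["members"] = [m.to_dict() for m in self.members]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        d = dict(d)
        d["members"] = tuple(cls.from_dict(m) for m in d.get("members", ()))
        return cls(**d)


DEFAULT_RF = ClassifierSpec("random-forest")
DEFAULT_SVM = ClassifierSpec("svm-rbf")


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


# --------------------------------------------------------------------------
# Cross-validation and grid search
# --------------------------------------------------------------------------

def cross_validate(
    X,
    y,
    spec: ClassifierSpec = DEFAULT_RF,
    folds: int = 10,
    seed: int = 0,
    fscore: str = "positive",
) -> MetricsReport:
    """Stratified k-fold CV with pooled out-of-fold confusion counts.

    Folds come from a seeded stratified shuffle; the same (data, spec,
    folds, seed) always yields the identical report.  Per-fold reports
    and fold assignments ride along on the returned
    :class:`MetricsReport`.
    """
    Xa = _as_array(X)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if Xa.shape[0] != n:
        raise EvaluationError("X and y row counts differ")
    if folds < 2:
        raise EvaluationError("folds must be >= 2")
    if n < folds:
        raise EvaluationError(f"n={n} < folds={folds}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise EvaluationError("both classes must be present")
    if counts.min() < folds:
        raise EvaluationError(
            f"minority class has {counts.min()} samples < folds={folds}; "
            "stratification impossible"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    fold_reports = []
    assignments = []
    for train_idx, test_idx in splitter.split(Xa, y):
        model = spec.build(seed)
        model.fit(Xa[train_idx], y[train_idx])
        pred = model.predict(Xa[test_idx])
        fold_counts = confusion(y[test_idx], pred)
        pooled = pooled + fold_counts
        fold_reports.append(metrics(fold_counts, fscore=fscore))
        assignments.append(test_idx.tolist())
    report = metrics(pooled, fscore=fscore)
    report.fold_reports = fold_reports
    report.fold_assignments = assignments
    return report


def default_c_grid() -> list[float]:
    """Powers of two 2^-5 .. 2^15, exponent step 2 (classic grid-search range)."""
    return [2.0 ** e for e in range(-5, 16, 2)]


def default_g_grid() -> list[float]:
    """Powers of two 2^-15 .. 2^3, exponent step 2."""
    return [2.0 ** e for e in range(-15, 4, 2)]


def grid_search_svm(
    X,
    y,
    c_grid: Sequence[float] | None = None,
    g_grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    fscore: str = "positive",
) -> tuple[float, float, MetricsReport]:
    """Exhaustive (c, g) grid search for the RBF SVM, maximising CV accuracy.

    Ties break toward smaller c, then smaller g, so results are
    deterministic.  Returns the winning (c, g) and its CV report.
    """
    c_grid = list(c_grid) if c_grid is not None else default_c_grid()
    g_grid = list(g_grid) if g_grid is not None else default_g_grid()
    if not c_grid or not g_grid:
        raise EvaluationError("grids must be non-empty")
    best: tuple[float, float, MetricsReport] | None = None
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            report = cross_validate(
                X, y, ClassifierSpec("svm-rbf", c=c, g=g),
                folds=folds, seed=seed, fscore=fscore,
            )
            if best is None or report.acc > best[2].acc:
                best = (c, g, report)
    assert best is not None
    return best


# --------------------------------------------------------------------------
# Final models
# --------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A fitted model plus everything needed to reproduce its predictions:
    the feature manifest, the classifier spec and the training seed."""

    model: object
    feature_names: list[str]
    spec: ClassifierSpec
    seed: int

    def predict_matrix(self, X: FeatureMatrix) -> np.ndarray:
        if X.names != self.feature_names:
            raise EvaluationError(
                f"input features ({len(X.names)} columns) do not match the "
                f"model manifest ({len(self.feature_names)} columns)"
            )
        return np.asarray(self.model.predict(X.values), dtype=int)

    def decision_scores(self, X: FeatureMatrix) -> np.ndarray:
        """A per-peptide score: decision function if available, else P(ACP)."""
        if X.names != self.feature_names:
            raise EvaluationError("input features do not match model manifest")
        model = self.model
        if hasattr(model, "decision_function"):
            return np.asarray(model.decision_function(X.values), dtype=float)
        if hasattr(model, "predict_proba"):
            return np.asarray(model.predict_proba(X.values)[:, 1], dtype=float)
        return self.predict_matrix(X).astype(float)

    def save(self, path: str | Path) -> None:
        payload = {
            "model": self.model,
            "feature_names": self.feature_names,
            "spec": self.spec.to_dict(),
            "seed": self.seed,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        payload = joblib.load(path)
        return cls(
            model=payload["model"],
            feature_names=list(payload["feature_names"]),
            spec=ClassifierSpec.from_dict(payload["spec"]),
            seed=int(payload["seed"]),
        )


def train_final(
    X: FeatureMatrix,
    y,
    spec: ClassifierSpec = DEFAULT_RF,
    seed: int = 0,
) -> ModelBundle:
    """Fit the classifier on all data and bundle it with its manifest."""
    model = spec.build(seed)
    model.fit(X.values, np.asarray(y, dtype=int))
    return ModelBundle(
        model=model, feature_names=X.names, spec=spec, seed=seed
    )


def report_frame(reports: dict[str, MetricsReport], percent: bool = True) -> pd.DataFrame:
    """Tabulate reports with the conventional comparison-table columns."""
    rows = {}
    for name, rep in reports.items():
        row = rep.as_dict(percent=percent)
        rows[name] = row
    frame = pd.DataFrame(rows).T
    frame.index.name = "Method"
    return frame[["Sn", "Sp", "Acc", "MCC", "F-score"]]
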