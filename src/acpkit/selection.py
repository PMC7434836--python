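"""Max-relevance–max-distance feature ranking and incremental subset evaluation.

The selection procedure is rank-then-incrementally-evaluate:

1. :func:`rank_features` scores every feature with an MRMD-style
   composite — relevance of the feature to the class label (absolute
   Pearson correlation by default) plus its mean distance to all other
   features (Euclidean on standardised columns by default, a redundancy
   penalty: a feature far from the rest carries non-duplicated
   information) — and sorts descending.
2. :func:`incremental_curve` evaluates the top-1, top-2, ..., top-d
   subsets by stratified cross-validation with a fixed classifier,
   producing the per-dimension metric curve.
3. :func:`select_best` picks the smallest dimension maximising the
   F-score; :func:`knee_points` extracts the slope-point features whose
   addition produced a large jump in the curve.
4. :func:`iterate_reduction` repeats rank → curve → select on the
   shrinking subset until the dimension stabilises, mirroring how
   repeated dimension reduction yields very low-dimensional models.

A sequential-forward :func:`greedy_select` is included for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .encoders import FeatureMatrix
from .evaluation import (
    DEFAULT_RF,
    ClassifierSpec,
    MetricsReport,
    _as_array,
    cross_validate,
)
from .sequence_io import AcpkitError


class SelectionError(AcpkitError):
    pass


# --------------------------------------------------------------------------
# Ranking
# --------------------------------------------------------------------------

@dataclass
class RankedFeatures:
    """Features ordered by descending composite score.

    Relevance and distance components are recorded separately so a
    ranking is auditable; the order is a permutation of the input
    feature set with deterministic tie-breaking (score, then name).
    """

    names: list[str]
    scores: np.ndarray
    relevance: np.ndarray
    distance: np.ndarray
    relevance_scorer: str = "pearson"
    distance_scorer: str = "euclidean"

    def top(self, m: int) -> list[str]:
        return self.names[:m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.names,
            "score": self.scores,
            "relevance": self.relevance,
            "distance": self.distance,
        })


def _standardize(Xa: np.ndarray) -> np.ndarray:
    mean = Xa.mean(axis=0)
    std = Xa.std(axis=0)
    Z = np.zeros_like(Xa)
    nz = std > 0
    Z[:, nz] = (Xa[:, nz] - mean[nz]) / std[nz]
    return Z


def _relevance_pearson(Xa: np.ndarray, y: np.ndarray) -> np.ndarray:
    # |Pearson r| per column; zero-variance columns get 0.  For binary y
    # this is also the point-biserial correlation.
    yc = y - y.mean()
    xc = Xa - Xa.mean(axis=0)
    num = xc.T @ yc
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    out = np.zeros(Xa.shape[1])
    nz = denom > 0
    out[nz] = np.abs(num[nz] / denom[nz])
    return out


def _relevance_anova_f(Xa: np.ndarray, y: np.ndarray) -> np.ndarray:
    from sklearn.feature_selection import f_classif

    f_stat, _ = f_classif(Xa, y)
    f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=0.0)
    # squash to [0, 1) so the composite stays on the relevance+distance scale
    return f_stat / (1.0 + f_stat)


def _mean_distances(Z: np.ndarray, kind: str) -> np.ndarray:
    """Mean distance of each (standardised) column to all other columns.

    Euclidean distances are divided by sqrt(n) so that the distance term
    is O(1) and commensurate with a correlation-based relevance term.
    """
    n, d = Z.shape
    if d == 1:
        return np.zeros(1)
    if kind == "euclidean":
        # chunked so wide matrices never materialise a d x d array
        sq = (Z ** 2).sum(axis=0)
        sums = np.zeros(d)
        block = 2048
        for start in range(0, d, block):
            stop = min(start + block, d)
            gram_blk = Z[:, start:stop].T @ Z  # (stop-start) x d
            d2 = sq[start:stop, None] + sq[None, :] - 2 * gram_blk
            dist_blk = np.sqrt(np.clip(d2, 0.0, None))
            idx = np.arange(start, stop)
            dist_blk[idx - start, idx] = 0.0
            sums[start:stop] = dist_blk.sum(axis=1)
        return sums / np.sqrt(n) / (d - 1)
    gram = Z.T @ Z  # d x d; the non-default scorers target modest d
    if kind == "cosine":
        norms = np.sqrt(np.clip(np.diag(gram), 1e-300, None))
        cos = gram / norms[:, None] / norms[None, :]
        dist = 1.0 - np.clip(cos, -1.0, 1.0)
        np.fill_diagonal(dist, 0.0)
    elif kind == "tanimoto":
        sq = np.diag(gram)
        denom = sq[:, None] + sq[None, :] - gram
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(np.abs(denom) > 1e-300, gram / denom, 0.0)
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
    else:
        raise SelectionError(f"unknown distance scorer {kind!r}")
    return dist.sum(axis=1) / (d - 1)


_RELEVANCE = {
    "pearson": _relevance_pearson,
    "point_biserial": _relevance_pearson,
    "anova_f": _relevance_anova_f,
}


def rank_features(
    X,
    y,
    relevance: str = "pearson",
    distance: str = "euclidean",
) -> RankedFeatures:
    """Score and sort features by the MRMD-style composite.

    score_i = relevance(feature_i, y) + mean distance of standardised
    feature i to all other features.  Requires n >= 4, at least one
    feature and both classes present.  Ties break by lexicographic
    feature name so rankings are reproducible across platforms.
    """
    Xa = _as_array(X)
    names = (
        X.names if isinstance(X, FeatureMatrix)
        else [f"f{i}" for i in range(Xa.shape[1])]
    )
    y = np.asarray(y, dtype=int)
    if Xa.shape[0] < 4:
        raise SelectionError("need at least 4 samples to rank features")
    if Xa.shape[1] < 1:
        raise SelectionError("need at least one feature")
    if len(np.unique(y)) < 2:
        raise SelectionError("both classes must be present to rank features")
    if relevance not in _RELEVANCE:
        raise SelectionError(f"unknown relevance scorer {relevance!r}")
    rel = _RELEVANCE[relevance](Xa, y)
    Z = _standardize(Xa)
    dist = _mean_distances(Z, distance)
    scores = rel + dist
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return RankedFeatures(
        names=[names[i] for i in order],
        scores=scores[order],
        relevance=rel[order],
        distance=dist[order],
        relevance_scorer=relevance,
        distance_scorer=distance,
    )


# --------------------------------------------------------------------------
# Incremental curve
# --------------------------------------------------------------------------

@dataclass
class SelectionCurve:
    """Per-dimension CV metrics for the nested top-m subsets of a ranking."""

    dims: np.ndarray
    reports: list[MetricsReport]
    ranking: RankedFeatures
    spec: ClassifierSpec
    folds: int
    seed: int

    def __post_init__(self) -> None:
        self.dims = np.asarray(self.dims, dtype=int)
        if len(self.dims) != len(self.reports):
            raise SelectionError("dims and reports length mismatch")
        if len(self.dims) and (np.diff(self.dims) <= 0).any():
            raise SelectionError("dimension axis must be strictly increasing")

    @property
    def f_scores(self) -> np.ndarray:
        return np.array([r.f_score for r in self.reports])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dimension": self.dims,
            "Sn": [r.sn for r in self.reports],
            "Sp": [r.sp for r in self.reports],
            "Acc": [r.acc for r in self.reports],
            "MCC": [r.mcc for r in self.reports],
            "F-score": self.f_scores,
        })

    def plot(self, path: str | Path, metric: str = "F-score") -> None:
        """Line chart of a metric against dimension (needs matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.to_frame()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(frame["dimension"], frame[metric], marker="o", ms=3)
        ax.set_xlabel("dimension")
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def incremental_curve(
    X,
    y,
    ranking: RankedFeatures,
    folds: int = 10,
    seed: int = 0,
    spec: ClassifierSpec = DEFAULT_RF,
    fscore: str = "positive",
) -> SelectionCurve:
    """Evaluate every nested top-m subset of a ranking by stratified CV.

    The highest-scoring feature is evaluated alone, then the second is
    added, and so on until all d features are in — one pooled
    cross-validation report per dimension.  Deterministic under a fixed
    seed; the point at m = d equals a direct :func:`cross_validate` call
    on the full matrix with the same seed.
    """
    Xa = _as_array(X)
    names = (
        X.names if isinstance(X, FeatureMatrix)
        else [f"f{i}" for i in range(Xa.shape[1])]
    )
    col = {n: i for i, n in enumerate(names)}
    missing = [n for n in ranking.names if n not in col]
    if missing:
        raise SelectionError(f"ranking features absent from X: {missing[:5]}")
    reports = []
    for m in range(1, len(ranking.names) + 1):
        idx = [col[n] for n in ranking.top(m)]
        reports.append(
            cross_validate(Xa[:, idx], y, spec=spec, folds=folds, seed=seed,
                           fscore=fscore)
        )
    return SelectionCurve(
        dims=np.arange(1, len(ranking.names) + 1),
        reports=reports,
        ranking=ranking,
        spec=spec,
        folds=folds,
        seed=seed,
    )


def select_best(curve: SelectionCurve) -> tuple[int, list[str]]:
    """Smallest dimension maximising the F-score, plus its feature names."""
    if len(curve.dims) == 0:
        raise SelectionError("empty selection curve")
    f = curve.f_scores
    best_idx = int(np.argmax(f))  # argmax takes the first (smallest m) on ties
    m = int(curve.dims[best_idx])
    return m, curve.ranking.top(m)


def knee_points(curve: SelectionCurve, min_gain: float = 0.01) -> list[str]:
    """Slope-point features: those whose addition raised the F-score by
    more than ``min_gain`` (with F-score(0) defined as 0).

    These are the red-dot features of a dimension/F-score line chart; at
    ``min_gain=0`` every feature with a strictly positive gain is
    returned.
    """
    if len(curve.dims) == 0:
        raise SelectionError("empty selection curve")
    if min_gain < 0:
        raise SelectionError("min_gain must be >= 0")
    f = curve.f_scores
    previous = np.concatenate([[0.0], f[:-1]])
    gains = f - previous
    out = []
    for i, gain in enumerate(gains):
        if gain > min_gain:
            out.append(curve.ranking.names[i])
    return out


# --------------------------------------------------------------------------
# Greedy forward selection
# --------------------------------------------------------------------------

@dataclass
class GreedyResult:
    names: list[str]
    trace: list[float]  # CV F-score after each accepted feature


def greedy_select(
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    spec: ClassifierSpec = DEFAULT_RF,
    fscore: str = "positive",
    max_features: int | None = None,
) -> GreedyResult:
    """Sequential forward selection maximising CV F-score.

    Starts from the empty set; at each step adds the feature whose
    inclusion yields the highest CV F-score (ties toward the
    lexicographically smaller name), and stops when no addition
    improves on the current score.
    """
    Xa = _as_array(X)
    names = (
        X.names if isinstance(X, FeatureMatrix)
        else [f"f{i}" for i in range(Xa.shape[1])]
    )
    chosen: list[int] = []
    trace: list[float] = []
    best_score = -np.inf
    remaining = list(range(len(names)))
    limit = max_features or len(names)
    while remaining and len(chosen) < limit:
        candidates = []
        for j in remaining:
            rep = cross_validate(
                Xa[:, chosen + [j]], y, spec=spec, folds=folds, seed=seed,
                fscore=fscore,
            )
            candidates.append((rep.f_score, names[j], j))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        top_score, _, top_j = candidates[0]
        if top_score <= best_score:
            break
        chosen.append(top_j)
        remaining.remove(top_j)
        best_score = top_score
        trace.append(top_score)
    return GreedyResult(names=[names[j] for j in chosen], trace=trace)


# --------------------------------------------------------------------------
# Iterated reduction
# --------------------------------------------------------------------------

@dataclass
class ReductionRound:
    dimension: int
    names: list[str]
    curve: SelectionCurve


def iterate_reduction(
    X: FeatureMatrix,
    y,
    folds: int = 10,
    seed: int = 0,
    spec: ClassifierSpec = DEFAULT_RF,
    relevance: str = "pearson",
    distance: str = "euclidean",
    min_gain: float = 0.01,
    max_iterations: int = 10,
    top: int | None = None,
    fscore: str = "positive",
) -> list[ReductionRound]:
    """Repeat rank → incremental curve → select-best on the shrinking subset.

    Runs until the selected dimension stops shrinking or
    ``max_iterations`` rounds have run.  ``top`` optionally truncates
    each ranking to its top-``top`` features before tracing the curve,
    which keeps very wide matrices tractable.  Returns the per-round
    curves so knee features can be pulled from the last chart.
    """
    if not isinstance(X, FeatureMatrix):
        raise SelectionError("iterate_reduction requires a FeatureMatrix")
    current = X
    rounds: list[ReductionRound] = []
    previous_dim = current.shape[1] + 1
    for _ in range(max_iterations):
        ranking = rank_features(current, y, relevance=relevance,
                                distance=distance)
        if top is not None and top < len(ranking.names):
            ranking = RankedFeatures(
                names=ranking.names[:top],
                scores=ranking.scores[:top],
                relevance=ranking.relevance[:top],
                distance=ranking.distance[:top],
                relevance_scorer=ranking.relevance_scorer,
                distance_scorer=ranking.distance_scorer,
            )
        curve = incremental_curve(
            current, y, ranking, folds=folds, seed=seed, spec=spec,
            fscore=fscore,
        )
        dim, chosen = select_best(curve)
        rounds.append(ReductionRound(dimension=dim, names=chosen, curve=curve))
        if dim >= previous_dim:
            break
        previous_dim = dim
        current = current.subset(chosen)
        if dim == 1:
            break
    return rounds
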