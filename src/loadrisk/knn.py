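"""From-scratch k-nearest-neighbors binary classifier.

The case probability of a query point is the fraction of case-labeled
rows among its k nearest training rows.  Distances are Euclidean,
Manhattan or cosine (1 - cosine similarity); ties in distance are broken
by training-row order (stable sort).  Classification uses the inclusive
rule ``probability >= threshold`` so a query exactly at the decision
cut-off is called a case — the sensitivity-first convention.

Also provided: class rebalancing of a training set (random oversampling
of the minority class or subsampling of the majority class to exact
parity), a stratified 70/30 train/test split, and 5-fold cross-validated
selection of k over a configurable grid (default: the 60 odd values
1, 3, ..., 119).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import (
    DegenerateDataError,
    InvalidParameterError,
    StratificationError,
)

METRICS = ("euclidean", "manhattan", "cosine")

#: 60 odd k values; odd k avoids 50/50 votes under the 0.5 threshold
DEFAULT_K_GRID = tuple(range(1, 120, 2))

# cap on temporary element count when materializing |a-b| blocks
_CHUNK_ELEMENTS = 2 ** 25


def _as_2d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def pairwise_distances(A, B, metric: str = "euclidean") -> np.ndarray:
    """Dense |A| x |B| distance matrix for one of the three metrics."""
    A, B = _as_2d(A), _as_2d(B)
    if A.shape[1] != B.shape[1]:
        raise InvalidParameterError("dimension mismatch between point sets")
    if A.shape[1] < 1:
        raise InvalidParameterError("points must have at least one coordinate")
    if metric == "euclidean":
        sq = (
            (A * A).sum(axis=1)[:, None]
            + (B * B).sum(axis=1)[None, :]
            - 2.0 * (A @ B.T)
        )
        return np.sqrt(np.clip(sq, 0.0, None))
    if metric == "manhattan":
        out = np.empty((A.shape[0], B.shape[0]))
        step = max(1, _CHUNK_ELEMENTS // (B.shape[0] * B.shape[1]))
        for i in range(0, A.shape[0], step):
            out[i : i + step] = np.abs(A[i : i + step, None, :] - B[None, :, :]).sum(
                axis=2
            )
        return out
    if metric == "cosine":
        na = np.linalg.norm(A, axis=1)
        nb = np.linalg.norm(B, axis=1)
        if (na == 0).any() or (nb == 0).any():
            raise DegenerateDataError("cosine distance undefined for zero vectors")
        return 1.0 - (A @ B.T) / np.outer(na, nb)
    raise InvalidParameterError(f"unknown metric {metric!r}")


def distance(a, b, metric: str = "euclidean") -> float:
    """Distance between two feature vectors."""
    return float(pairwise_distances(_as_2d(a), _as_2d(b), metric)[0, 0])


def _neighbor_label_matrix(train_X, train_y, query_X, metric) -> np.ndarray:
    """Labels of every training row, sorted by distance per query
    (stable: distance ties keep training-row order)."""
    D = pairwise_distances(query_X, train_X, metric)
    order = np.argsort(D, axis=1, kind="stable")
    return np.asarray(train_y)[order]


def knn_probabilities(train_X, train_y, query_X, k: int, metric: str = "euclidean") -> np.ndarray:
    """Case probability per query row: case fraction among the k nearest."""
    train_X, query_X = _as_2d(train_X), _as_2d(query_X)
    train_y = np.asarray(train_y)
    if not 1 <= k <= train_X.shape[0]:
        raise InvalidParameterError(
            f"k={k} outside [1, {train_X.shape[0]}] for this training set"
        )
    labels_sorted = _neighbor_label_matrix(train_X, train_y, query_X, metric)
    return labels_sorted[:, :k].mean(axis=1)


def knn_probability(train_X, train_y, query, k: int, metric: str = "euclidean") -> float:
    """Single-query convenience wrapper."""
    return float(knn_probabilities(train_X, train_y, _as_2d(query), k, metric)[0])


def classify(prob, threshold: float = 0.5):
    """Case iff probability >= threshold (boundary inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise InvalidParameterError("threshold must lie in [0, 1]")
    p = np.asarray(prob, dtype=float)
    out = (p >= threshold).astype(int)
    return out if p.ndim else int(out)


def select_k(
    train_X,
    train_y,
    metric: str = "euclidean",
    k_grid=None,
    folds: int = 5,
    seed: int = 0,
    criterion: str = "accuracy",
) -> tuple[int, pd.DataFrame]:
    """Stratified cross-validated choice of k.

    Per candidate k, mean validation accuracy (threshold 0.5) across
    ``folds`` stratified folds (or mean AUC with ``criterion='auc'``);
    the best k is the smallest argmax.  Candidates exceeding the
    smallest fold's training size are skipped.
    """
    from .evaluation import roc_and_auc  # local import, avoids cycle

    train_X = _as_2d(train_X)
    train_y = np.asarray(train_y)
    if folds < 2:
        raise InvalidParameterError("folds must be >= 2")
    if criterion not in ("accuracy", "auc"):
        raise InvalidParameterError(f"unknown criterion {criterion!r}")
    if len(np.unique(train_y)) < 2:
        raise StratificationError("training data must contain both classes")
    if np.bincount(train_y.astype(int)).min() < folds:
        raise StratificationError(
            "minority class too small for the requested number of folds"
        )
    k_grid = np.asarray(DEFAULT_K_GRID if k_grid is None else k_grid, dtype=int)
    min_train = int(np.floor(len(train_y) * (folds - 1) / folds))
    usable = k_grid[k_grid <= min_train]
    if usable.size == 0:
        raise InvalidParameterError("no candidate k fits the fold training size")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros((folds, usable.size))
    for f, (tr, va) in enumerate(skf.split(train_X, train_y)):
        labels_sorted = _neighbor_label_matrix(
            train_X[tr], train_y[tr], train_X[va], metric
        )
        cumulative = np.cumsum(labels_sorted, axis=1)
        for j, k in enumerate(usable):
            prob = cumulative[:, k - 1] / k
            if criterion == "accuracy":
                scores[f, j] = np.mean((prob >= 0.5).astype(int) == train_y[va])
            else:
                scores[f, j] = roc_and_auc(train_y[va], prob)[1]
    mean_scores = scores.mean(axis=0)
    best_k = int(usable[int(np.argmax(mean_scores))])  # argmax -> smallest k on ties
    cv_table = pd.DataFrame({"k": usable, "cv_score": mean_scores})
    return best_k, cv_table


def rebalance(
    train_X: pd.DataFrame | np.ndarray,
    train_y,
    strategy: str = "none",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance training classes to exact parity.

    ``oversample`` duplicates minority rows uniformly at random with
    replacement until the counts match (all original rows are retained);
    ``subsample`` draws majority rows without replacement down to the
    minority count; ``none`` returns the input unchanged.
    """
    X = _as_2d(train_X) if not isinstance(train_X, pd.DataFrame) else train_X.to_numpy()
    y = np.asarray(train_y).astype(int)
    if strategy not in ("none", "oversample", "subsample"):
        raise InvalidParameterError(f"unknown sampling strategy {strategy!r}")
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise DegenerateDataError("rebalancing needs both classes present")
    if strategy == "none" or counts[0] == counts[1]:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    minority = int(np.argmin(counts))
    idx_min = np.where(y == minority)[0]
    idx_maj = np.where(y != minority)[0]
    if strategy == "oversample":
        extra = rng.choice(idx_min, size=counts.max() - counts.min(), replace=True)
        keep = np.concatenate([np.arange(len(y)), extra])
    else:
        kept_maj = rng.choice(idx_maj, size=counts.min(), replace=False)
        keep = np.sort(np.concatenate([idx_min, kept_maj]))
    return X[keep], y[keep]


@dataclass(frozen=True)
class SplitIndex:
    """Positional train/test indices of a stratified split."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    test_fraction: float
    seed: int


def split(
    n_or_y,
    test_fraction: float = 0.30,
    seed: int = 0,
    stratified: bool = True,
) -> SplitIndex:
    """70/30-style random split; stratified by label by default.

    ``n_or_y`` is the label vector (required for stratification) or a
    row count for an unstratified split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise InvalidParameterError("test_fraction must lie in (0, 1)")
    if np.isscalar(n_or_y):
        y = None
        idx = np.arange(int(n_or_y))
    else:
        y = np.asarray(n_or_y)
        idx = np.arange(len(y))
    tr, te = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=y if stratified else None,
        shuffle=True,
    )
    return SplitIndex(
        train_idx=np.sort(tr),
        test_idx=np.sort(te),
        test_fraction=test_fraction,
        seed=seed,
    )


@dataclass
class KnnModel:
    """A trained (memorized) KNN classifier, serializable to JSON."""

    train_X: np.ndarray
    train_y: np.ndarray
    k: int
    metric: str = "euclidean"
    threshold: float = 0.5
    feature_names: list[str] = field(default_factory=list)

    def predict_proba(self, X) -> np.ndarray:
        return knn_probabilities(self.train_X, self.train_y, X, self.k, self.metric)

    def predict(self, X) -> np.ndarray:
        return classify(self.predict_proba(X), self.threshold)

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "metric": self.metric,
            "threshold": self.threshold,
            "feature_names": list(self.feature_names),
            "train_X": self.train_X.tolist(),
            "train_y": self.train_y.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "KnnModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            train_X=np.asarray(payload["train_X"], dtype=float),
            train_y=np.asarray(payload["train_y"], dtype=int),
            k=int(payload["k"]),
            metric=payload["metric"],
            threshold=float(payload["threshold"]),
            feature_names=payload["feature_names"],
        )
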