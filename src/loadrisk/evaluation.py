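"""Classifier evaluation: confusion metrics, ROC/AUC, threshold sweep.

The positive class is "case".  The ROC curve is built by sweeping every
distinct predicted probability as a threshold with the inclusive
``>= threshold`` rule used by the classifier, plus the (0,0) and (1,1)
endpoints; the AUC is the trapezoid area.  KNN probabilities are
multiples of 1/k, so ties are common: the trapezoid over a tied block
gives half credit, which makes the AUC identical to the tie-corrected
concordance (Mann-Whitney) statistic.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidParameterError, NoThresholdError
from .knn import classify

#: default sweep grid — every multiple of 0.01 in [0, 1]
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.linspace(0.0, 1.0, 101), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels, predicted) -> ConfusionCounts:
    """Confusion counts with case (1) as the positive class."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predicted).astype(int)
    if y.shape != p.shape:
        raise InvalidParameterError("labels and predictions differ in length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise InvalidParameterError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (0/0); reported as NaN", RuntimeWarning,
                      stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, precision and F1 from counts.

    Ratios with a zero denominator are reported as NaN with a warning.
    """
    sens = _safe_ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _safe_ratio(c.tn, c.tn + c.fp, "specificity")
    acc = _safe_ratio(c.tp + c.tn, c.n, "accuracy")
    prec = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan")
        if not np.isnan(prec) and not np.isnan(sens):
            warnings.warn("F1 undefined (0/0); reported as NaN", RuntimeWarning)
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "precision": prec,
        "f1": f1,
    }


def roc_and_auc(labels, probabilities) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr) and trapezoid AUC.

    Equals the concordance probability with half credit for tied
    probabilities; raises on single-class labels.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise InvalidParameterError("labels and probabilities differ in length")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise InvalidParameterError("probabilities must lie in [0, 1]")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("AUC undefined for single-class labels")

    points = [(0.0, 0.0)]
    for t in np.unique(p)[::-1]:  # descending thresholds, >= rule
        pred = p >= t
        points.append(
            (
                float((pred & (y == 0)).sum()) / n_neg,
                float((pred & (y == 1)).sum()) / n_pos,
            )
        )
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    roc = np.asarray(points)
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return roc, auc


def threshold_sweep(labels, probabilities, grid=None) -> pd.DataFrame:
    """Sensitivity/specificity at each threshold of ``grid`` (>= rule).

    Sensitivity is non-increasing and specificity non-decreasing in the
    threshold by construction.
    """
    grid = np.asarray(DEFAULT_THRESHOLD_GRID if grid is None else grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > 1):
        raise InvalidParameterError("thresholds must lie in [0, 1]")
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-class NaNs
        for t in np.sort(grid):
            m = metrics(confusion(y, classify(p, t)))
            rows.append((t, m["sensitivity"], m["specificity"]))
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])


def optimal_threshold(
    sweep: pd.DataFrame,
    policy: str = "youden",
    min_specificity: float | None = None,
) -> float:
    """Pick a threshold from a sweep table.

    ``youden`` maximizes sensitivity + specificity - 1; ``constrained``
    returns the smallest threshold whose specificity is at least
    ``min_specificity`` (hence the largest feasible sensitivity).  Ties
    resolve to the lower threshold.
    """
    if sweep.empty:
        raise InvalidParameterError("empty sweep table")
    if policy == "youden":
        j = sweep["sensitivity"] + sweep["specificity"] - 1.0
        return float(sweep.loc[j.idxmax(), "threshold"])  # idxmax -> first/lowest
    if policy == "constrained":
        if min_specificity is None:
            raise InvalidParameterError("constrained policy needs min_specificity")
        ok = sweep[sweep["specificity"] >= min_specificity]
        if ok.empty:
            raise NoThresholdError(
                f"no threshold reaches specificity {min_specificity}"
            )
        return float(ok["threshold"].min())
    raise InvalidParameterError(f"unknown policy {policy!r}")


@dataclass
class EvalReport:
    """Full test-set evaluation of one model."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    auc: float
    threshold: float
    n_test: int
    confusion: ConfusionCounts
    roc_points: np.ndarray

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "sensitivity", "specificity", "accuracy",
                "precision", "f1", "auc", "threshold", "n_test",
            )
        }
        d["confusion"] = dataclasses.asdict(self.confusion)
        d["roc_points"] = np.asarray(self.roc_points).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def evaluate(labels, probabilities, threshold: float = 0.5) -> EvalReport:
    """Evaluate predicted case probabilities against true labels."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    c = confusion(y, classify(p, threshold))
    m = metrics(c)
    roc, auc = roc_and_auc(y, p)
    return EvalReport(
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        accuracy=m["accuracy"],
        precision=m["precision"],
        f1=m["f1"],
        auc=auc,
        threshold=threshold,
        n_test=len(y),
        confusion=c,
        roc_points=roc,
    )
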