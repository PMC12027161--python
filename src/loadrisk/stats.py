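"""Case/control inferential statistics for the model's predictors.

Numeric predictors (z-score, age, cholesterol) are compared with
Welch's unequal-variance t-test and Hedges' g (small-sample-corrected
standardized mean difference, sign = case mean minus control mean).
Categorical predictors (APOE code, sex, smoking, diabetes) use the
Pearson chi-square independence test without continuity correction and
Cramer's V.  The APOE battery adds a per-diplotype-group goodness-of-fit
test of each group's case/control split against the cohort-wide
proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InvalidParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NumericTestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    hedges_g: float


@dataclass(frozen=True)
class CategoricalTestResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float
    cramers_v: float


def hedges_g(x, y) -> float:
    """Hedges' g = J * (mean(x) - mean(y)) / s_pooled with
    J = 1 - 3 / (4(n_x + n_y) - 9)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise InvalidParameterError("each group needs at least two observations")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    s_pooled = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    if s_pooled == 0:
        raise DegenerateDataError("zero pooled SD")
    correction = 1.0 - 3.0 / (4.0 * (nx + ny) - 9.0)
    return float(correction * (np.mean(x) - np.mean(y)) / s_pooled)


def welch_test(x, y) -> NumericTestResult:
    """Welch two-sample t-test (x = cases, y = controls), two-sided p,
    with Hedges' g attached."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise InvalidParameterError("each group needs at least two observations")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        raise DegenerateDataError("both groups have zero variance")
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return NumericTestResult(
        statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=float(p),
        hedges_g=hedges_g(x, y),
    )


def chi_square_independence(table, correction: bool = False) -> CategoricalTestResult:
    """Pearson chi-square on a 2 x C contingency table, plus Cramer's V.

    ``correction=True`` applies the Yates continuity correction (2x2
    only); the default is uncorrected.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise InvalidParameterError("expected a 2 x C contingency table")
    if (t < 0).any():
        raise InvalidParameterError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateDataError("zero row or column margin")
    expected = np.outer(rows, cols) / n
    diff = np.abs(t - expected)
    if correction and t.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    v = float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))
    return CategoricalTestResult(
        chi_square=chi2, degrees_of_freedom=df, p_value=p, cramers_v=v
    )


def apoe_group_tests(
    apoe_codes, labels
) -> tuple[CategoricalTestResult | None, dict[int, CategoricalTestResult]]:
    """Overall 2 x G chi-square over APOE risk groups plus, per group,
    a df-1 goodness-of-fit of that group's case/control split against
    the cohort-wide case/control proportions.

    Returns ``(overall, per_group)``; the overall test is None when only
    one group is present.  Empty expected cells skip a group with a
    warning.
    """
    codes = np.asarray(apoe_codes)
    y = np.asarray(labels).astype(int)
    if codes.shape != y.shape:
        raise InvalidParameterError("codes and labels differ in length")
    groups = np.unique(codes)
    n = len(y)
    p_case = y.mean()
    per_group: dict[int, CategoricalTestResult] = {}
    table = []
    for g in groups:
        mask = codes == g
        n_g = int(mask.sum())
        cases = int(y[mask].sum())
        table.append((cases, n_g - cases))
        expected = np.array([n_g * p_case, n_g * (1 - p_case)])
        if (expected == 0).any():
            logger.warning("APOE group %s skipped: empty expected cell", g)
            continue
        observed = np.array([cases, n_g - cases], dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        per_group[int(g)] = CategoricalTestResult(
            chi_square=chi2,
            degrees_of_freedom=1,
            p_value=float(sps.chi2.sf(chi2, 1)),
            cramers_v=float(np.sqrt(chi2 / n_g)),
        )
    overall = None
    if len(groups) >= 2:
        overall = chi_square_independence(np.asarray(table, dtype=float).T)
    return overall, per_group


NUMERIC_PREDICTORS = ("z_score", "age", "cholesterol")
BINARY_PREDICTORS = ("sex", "smoker", "diabetes")


def cohort_summary(features: pd.DataFrame, labels) -> dict:
    """Run the full test battery on a feature matrix.

    Returns a dict with a :class:`NumericTestResult` per numeric
    predictor, a :class:`CategoricalTestResult` per binary predictor,
    and the overall + per-group APOE results.
    """
    y = np.asarray(labels).astype(int)
    out: dict = {"numeric": {}, "categorical": {}, "apoe": {}}
    for col in NUMERIC_PREDICTORS:
        if col in features:
            out["numeric"][col] = welch_test(
                features.loc[y == 1, col], features.loc[y == 0, col]
            )
    for col in BINARY_PREDICTORS:
        if col in features:
            x = features[col].to_numpy().astype(int)
            table = np.array(
                [
                    [((y == 1) & (x == v)).sum() for v in (0, 1)],
                    [((y == 0) & (x == v)).sum() for v in (0, 1)],
                ],
                dtype=float,
            )
            try:
                out["categorical"][col] = chi_square_independence(table)
            except DegenerateDataError:
                logger.warning("predictor %s degenerate; skipped", col)
    if "apoe" in features:
        overall, per_group = apoe_group_tests(
            features["apoe"].to_numpy().astype(int), y
        )
        out["apoe"] = {"overall": overall, "per_group": per_group}
    return out


def summary_to_dict(summary: dict) -> dict:
    """JSON-serializable form of :func:`cohort_summary` output."""
    def conv(r):
        return None if r is None else r.__dict__.copy()

    return {
        "numeric": {k: conv(v) for k, v in summary["numeric"].items()},
        "categorical": {k: conv(v) for k, v in summary["categorical"].items()},
        "apoe": {
            "overall": conv(summary["apoe"].get("overall")),
            "per_group": {
                str(k): conv(v)
                for k, v in summary["apoe"].get("per_group", {}).items()
            },
        } if summary.get("apoe") else {},
    }
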