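"""Feature construction for the risk model.

The genetic score for individual *j* is

    z_j = ( sum_i (g_ij + 1) * b_i  -  mu_control ) / sigma_control

where ``g_ij`` is the risk-oriented effect-allele dosage of SNP *i*
(0/1/2, so ``g + 1`` codes protective homozygotes as 1, heterozygotes
as 2 and risk homozygotes as 3), ``b_i`` the GWAS effect size, and
``mu_control`` / ``sigma_control`` the mean and SD (n-1 denominator) of
the raw weighted sum over the control group.  Orientation: a SNP with a
negative beta has its dosage flipped (``g = 2 - d``) and its beta
replaced by ``|b|``, so the "risk homozygote" is always the
beta-increasing one.  Because standardization is affine-invariant, both
the ``+1`` offset and the orientation convention leave z-scores
unchanged relative to signed-beta scoring.

The module also calls APOE diplotypes from the unphased rs429358 /
rs7412 genotypes, encodes the clinical covariates, assembles the
complete-case feature matrix, and provides train-fitted column scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateDataError, InvalidParameterError

logger = logging.getLogger(__name__)

#: fixed column order of the combined feature matrix
FEATURE_COLUMNS = ("z_score", "apoe", "age", "sex", "smoker", "diabetes", "cholesterol")

MISSING_POLICIES = ("control_mean", "overall_mean", "zero")


# ---------------------------------------------------------------------------
# weighted genetic score
# ---------------------------------------------------------------------------

def orient_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Return summary stats with non-negative betas and a ``flipped`` flag.

    ``stats`` needs columns ``snp_id``, ``effect_allele``, ``other_allele``,
    ``beta``.  For flipped SNPs the effect/other alleles are swapped so the
    effect allele is always the risk allele.
    """
    required = {"snp_id", "effect_allele", "other_allele", "beta"}
    missing = required - set(stats.columns)
    if missing:
        raise InvalidParameterError(f"summary stats missing columns: {sorted(missing)}")
    if stats["snp_id"].duplicated().any():
        raise InvalidParameterError("duplicate SNP ids in summary stats")
    out = stats.copy()
    flip = out["beta"] < 0
    out["flipped"] = flip.to_numpy()
    ea = out["effect_allele"].where(~flip, out["other_allele"])
    oa = out["other_allele"].where(~flip, out["effect_allele"])
    out["effect_allele"], out["other_allele"] = ea, oa
    out["beta"] = out["beta"].abs()
    return out


def oriented_dosages(G: pd.DataFrame, stats: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Align a dosage matrix to summary stats and orient it toward risk.

    Returns ``(G_oriented, betas)`` where flipped SNPs have dosage
    ``2 - d`` and all betas are non-negative.  Missing stays missing.
    """
    oriented = orient_stats(stats).set_index("snp_id")
    missing_snps = oriented.index.difference(G.columns)
    if len(missing_snps):
        raise AlignmentError(
            f"{len(missing_snps)} summary-stat SNPs absent from genotypes: "
            f"{list(missing_snps[:5])}"
        )
    g = G[oriented.index].astype(float)
    flip = oriented["flipped"].to_numpy()
    vals = g.to_numpy(copy=True)
    vals[:, flip] = 2.0 - vals[:, flip]
    return pd.DataFrame(vals, index=g.index, columns=g.columns), oriented["beta"]


def raw_weighted_scores(
    G: pd.DataFrame,
    stats: pd.DataFrame,
    missing_policy: str = "control_mean",
    control_mask: pd.Series | np.ndarray | None = None,
    offset: float = 1.0,
) -> pd.Series:
    """Per-individual raw weighted sum ``sum_i (g_i + offset) * b_i``.

    Missing dosages are imputed before summation according to
    ``missing_policy``:

    * ``control_mean`` — mean oriented dosage of that SNP over controls
      (requires ``control_mask``; the default, leakage-safe when the mask
      marks training controls only),
    * ``overall_mean`` — mean oriented dosage over everyone,
    * ``zero`` — protective-homozygote fill.
    """
    if missing_policy not in MISSING_POLICIES:
        raise InvalidParameterError(f"unknown missing policy {missing_policy!r}")
    g, beta = oriented_dosages(G, stats)
    vals = g.to_numpy(copy=True)
    if np.isnan(vals).any():
        if missing_policy == "zero":
            fill = np.zeros(vals.shape[1])
        elif missing_policy == "overall_mean":
            fill = np.nanmean(vals, axis=0)
        else:
            if control_mask is None:
                raise InvalidParameterError(
                    "control_mean imputation needs a control_mask"
                )
            mask = np.asarray(control_mask, dtype=bool)
            if mask.shape[0] != vals.shape[0]:
                raise AlignmentError("control_mask length mismatch")
            fill = np.nanmean(vals[mask], axis=0)
        fill = np.nan_to_num(fill, nan=0.0)  # SNP unobserved in the fill group
        idx = np.where(np.isnan(vals))
        vals[idx] = fill[idx[1]]
    raw = (vals + offset) @ beta.to_numpy()
    return pd.Series(raw, index=G.index, name="raw_score")


def raw_weighted_score(
    dosages: pd.Series | np.ndarray,
    stats: pd.DataFrame,
    missing_policy: str = "zero",
) -> float:
    """Single-individual convenience wrapper around :func:`raw_weighted_scores`."""
    if isinstance(dosages, pd.Series):
        frame = dosages.to_frame().T
    else:
        frame = pd.DataFrame(
            np.asarray(dosages, dtype=float)[None, :], columns=stats["snp_id"]
        )
    return float(raw_weighted_scores(frame, stats, missing_policy=missing_policy).iloc[0])


@dataclass(frozen=True)
class ScoreStandardization:
    """Control-group location/scale used to standardize raw scores."""

    mu_control: float
    sigma_control: float

    def __post_init__(self):
        if not self.sigma_control > 0:
            raise DegenerateDataError("sigma_control must be positive")


def standardize_scores(
    raw_scores: pd.Series, control_mask: pd.Series | np.ndarray
) -> tuple[pd.Series, ScoreStandardization]:
    """Z-standardize raw scores against the control group (n-1 SD)."""
    mask = np.asarray(control_mask, dtype=bool)
    if mask.shape[0] != len(raw_scores):
        raise AlignmentError("control_mask length mismatch")
    controls = raw_scores.to_numpy()[mask]
    if controls.size < 2:
        raise DegenerateDataError("need at least two controls to standardize")
    mu = float(np.mean(controls))
    sigma = float(np.std(controls, ddof=1))
    if sigma == 0.0:
        raise DegenerateDataError("control scores have zero variance")
    std = ScoreStandardization(mu_control=mu, sigma_control=sigma)
    z = (raw_scores - mu) / sigma
    return z.rename("z_score"), std


# ---------------------------------------------------------------------------
# APOE diplotype calling
# ---------------------------------------------------------------------------

#: ordinal risk code per diplotype (epsilon-haplotype pair)
APOE_CODES = {
    "e2/e2": -1, "e2/e3": -1,
    "e3/e3": 0,
    "e2/e4": 1, "e3/e4": 1,
    "e4/e4": 2,
    # epsilon-1 carriers (C at rs429358 with T at rs7412 on one haplotype)
    # are vanishingly rare; epsilon-1 shares the rs429358 risk allele with
    # epsilon-4 and is coded as epsilon-4-equivalent.
    "e1/e2": 1, "e1/e3": 1, "e1/e4": 2, "e1/e1": 2,
}


@dataclass(frozen=True)
class ApoeDiplotype:
    """A resolved APOE haplotype pair and its ordinal risk code."""

    value: str
    ordinal_code: int


def call_apoe_diplotype(rs429358_gt: int, rs7412_gt: int) -> ApoeDiplotype:
    """Resolve a diplotype from the C-allele counts at rs429358 and rs7412.

    Haplotype definitions (rs429358, rs7412): e2 = (T, T), e3 = (T, C),
    e4 = (C, C), e1 = (C, T).  The unphased double heterozygote (1, 1)
    resolves to e2/e4, the standard convention given e1's rarity; pairings
    that force an e1 haplotype are coded as e4-equivalent risk.
    """
    c1, c2 = int(rs429358_gt), int(rs7412_gt)
    if c1 not in (0, 1, 2) or c2 not in (0, 1, 2):
        raise InvalidParameterError("APOE genotypes must be C-allele counts 0/1/2")
    n_e4 = min(c1, c2)          # (C, C) pairs
    n_e1 = c1 - n_e4            # leftover C at rs429358 pairs with T at rs7412
    n_e2 = 2 - max(c1, c2)      # (T, T) pairs
    n_e3 = 2 - n_e4 - n_e1 - n_e2
    haps = ["e1"] * n_e1 + ["e2"] * n_e2 + ["e3"] * n_e3 + ["e4"] * n_e4
    value = "/".join(sorted(haps))
    if n_e1:
        logger.info("rare epsilon-1-implying genotype (%d, %d) -> %s", c1, c2, value)
    return ApoeDiplotype(value=value, ordinal_code=APOE_CODES[value])


def apoe_codes(apoe: pd.DataFrame) -> pd.Series:
    """Vectorized diplotype codes from a frame with rs429358/rs7412 columns."""
    codes = [
        call_apoe_diplotype(a, b).ordinal_code
        for a, b in zip(apoe["rs429358"], apoe["rs7412"])
    ]
    return pd.Series(codes, index=apoe.index, name="apoe")


# ---------------------------------------------------------------------------
# phenotype encoding and feature assembly
# ---------------------------------------------------------------------------

def encode_phenotypes(raw: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate columns: binaries validated as 0/1, age and
    cholesterol passed through, missing values preserved as NaN."""
    out = pd.DataFrame(index=raw.index)
    for col in ("sex", "smoker", "diabetes"):
        vals = pd.to_numeric(raw[col], errors="coerce") if col in raw else pd.Series(
            np.nan, index=raw.index
        )
        bad = vals.dropna()[~vals.dropna().isin((0, 1))]
        if len(bad):
            raise InvalidParameterError(
                f"non-binary {col} value for ids {list(bad.index[:5])}"
            )
        out[col] = vals.astype(float)
    for col in ("age", "cholesterol"):
        out[col] = pd.to_numeric(raw[col], errors="coerce") if col in raw else np.nan
    return out


def build_feature_matrix(
    z: pd.Series,
    apoe_code: pd.Series,
    encoded: pd.DataFrame,
    labels: pd.Series,
) -> tuple[pd.DataFrame, pd.Series, list]:
    """Join score, APOE code and covariates; drop rows with any missing value.

    Returns ``(X, labels, dropped_ids)`` with X columns in the fixed order
    :data:`FEATURE_COLUMNS`.
    """
    for other in (apoe_code, encoded, labels):
        if not z.index.equals(other.index):
            raise AlignmentError("feature inputs must share one id order")
    X = pd.DataFrame(
        {
            "z_score": z,
            "apoe": apoe_code.astype(float),
            "age": encoded["age"],
            "sex": encoded["sex"],
            "smoker": encoded["smoker"],
            "diabetes": encoded["diabetes"],
            "cholesterol": encoded["cholesterol"],
        }
    )[list(FEATURE_COLUMNS)]
    complete = X.notna().all(axis=1)
    dropped = list(X.index[~complete])
    if dropped:
        logger.info("dropped %d incomplete rows", len(dropped))
    return X[complete], labels[complete], dropped


@dataclass(frozen=True)
class ColumnScaling:
    """Training-set column means and SDs (n-1); constant columns get scale 1."""

    means: pd.Series
    sds: pd.Series

    def to_dict(self) -> dict:
        return {"means": self.means.to_dict(), "sds": self.sds.to_dict()}


def fit_scaler(train: pd.DataFrame) -> ColumnScaling:
    """Fit per-column z-scaling on training data only (leakage guard)."""
    if train.shape[0] < 2:
        raise InvalidParameterError("need at least two training rows to fit a scaler")
    means = train.mean()
    sds = train.std(ddof=1)
    constant = sds == 0.0
    if constant.any():
        logger.warning("constant columns scaled by 1: %s", list(train.columns[constant]))
        sds = sds.mask(constant, 1.0)
    return ColumnScaling(means=means, sds=sds)


def apply_scaler(scaling: ColumnScaling, X: pd.DataFrame) -> pd.DataFrame:
    return (X - scaling.means) / scaling.sds


def invert_scaler(scaling: ColumnScaling, X: pd.DataFrame) -> pd.DataFrame:
    return X * scaling.sds + scaling.means
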