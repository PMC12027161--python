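"""Genotype quality control.

Four exclusion rules are applied to an individuals x SNPs dosage matrix
(values 0/1/2 counting effect alleles, ``NaN`` for missing):

* SNPs with zero variance across observed genotypes,
* SNPs with a missing genotype rate strictly greater than ``max_missing``,
* SNPs with minor allele frequency strictly below ``min_maf``,
* individuals with a missing fraction strictly greater than ``max_missing``
  across the SNPs that survived the SNP-level filters.

Thresholds are strict: a SNP missing exactly 10% of genotypes, or with
MAF exactly 0.01, is retained.  SNP statistics are computed on the full
individual set; the individual filter then runs once on the SNP-filtered
matrix (no iteration to a fixed point unless ``iterate=True``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

#: reason labels, in precedence order used when several rules match
REASON_ZERO_VARIANCE = "zero_variance"
REASON_HIGH_MISSINGNESS = "high_missingness"
REASON_LOW_MAF = "low_maf"


def validate_genotypes(G: pd.DataFrame) -> pd.DataFrame:
    """Check a genotype matrix: unique ids, dosages in {0, 1, 2, NaN}."""
    if G.index.has_duplicates:
        raise InvalidParameterError("duplicate individual ids in genotype matrix")
    if G.columns.has_duplicates:
        raise InvalidParameterError("duplicate SNP ids in genotype matrix")
    vals = G.to_numpy(dtype=float)
    observed = vals[~np.isnan(vals)]
    if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
        bad = np.unique(observed[~np.isin(observed, (0.0, 1.0, 2.0))])
        raise InvalidParameterError(f"dosages outside {{0,1,2}}: {bad[:5]}")
    return G


@dataclass
class QcReport:
    """What was removed and why.

    ``removed_snps`` holds ``(snp_id, reason)`` pairs with reason one of
    ``zero_variance`` / ``high_missingness`` / ``low_maf``;
    ``removed_individuals`` holds ``(individual_id, "high_missingness")``.
    """

    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    removed_individuals: list[tuple[str, str]] = field(default_factory=list)
    n_snps_before: int = 0
    n_snps_after: int = 0
    n_individuals_before: int = 0
    n_individuals_after: int = 0

    @property
    def removed_snp_ids(self) -> list[str]:
        return [s for s, _ in self.removed_snps]

    @property
    def removed_individual_ids(self) -> list[str]:
        return [i for i, _ in self.removed_individuals]

    def to_dict(self) -> dict:
        return {
            "removed_snps": [list(t) for t in self.removed_snps],
            "removed_individuals": [list(t) for t in self.removed_individuals],
            "n_snps_before": self.n_snps_before,
            "n_snps_after": self.n_snps_after,
            "n_individuals_before": self.n_individuals_before,
            "n_individuals_after": self.n_individuals_after,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_snp_stats(G: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP missing rate, MAF, observed variance and observed count.

    MAF is ``min(f, 1 - f)`` with ``f`` the effect-allele frequency over
    observed genotypes only.  A SNP with zero observed genotypes gets
    ``missing_rate`` 1, variance 0 and MAF ``NaN`` (flagged, and treated
    as zero-variance by the filters).
    """
    if G.shape[0] == 0 or G.shape[1] == 0:
        raise InvalidParameterError("empty genotype matrix")
    vals = G.to_numpy(dtype=float)
    n_ind = vals.shape[0]
    observed = ~np.isnan(vals)
    n_obs = observed.sum(axis=0)
    missing_rate = 1.0 - n_obs / n_ind

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        dosage_sum = np.nansum(vals, axis=0)
        f = np.where(n_obs > 0, dosage_sum / np.maximum(2 * n_obs, 1), np.nan)
        maf = np.minimum(f, 1.0 - f)
        variance = np.nanvar(vals, axis=0)
    variance = np.where(n_obs > 0, variance, 0.0)

    return pd.DataFrame(
        {
            "missing_rate": missing_rate,
            "maf": maf,
            "variance": variance,
            "n_observed": n_obs,
        },
        index=G.columns,
    )


def filter_snps(
    G: pd.DataFrame, max_missing: float = 0.10, min_maf: float = 0.01
) -> tuple[pd.DataFrame, QcReport]:
    """Drop SNPs violating the variance / missingness / MAF rules.

    A removed SNP is reported with the first matching reason, in the
    order zero_variance, high_missingness, low_maf.
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise InvalidParameterError("thresholds must lie in [0, 1]")
    stats = compute_snp_stats(G)
    report = QcReport(
        n_snps_before=G.shape[1],
        n_individuals_before=G.shape[0],
        n_individuals_after=G.shape[0],
    )
    keep = []
    for snp, row in stats.iterrows():
        if row["variance"] == 0.0:
            report.removed_snps.append((snp, REASON_ZERO_VARIANCE))
        elif row["missing_rate"] > max_missing:
            report.removed_snps.append((snp, REASON_HIGH_MISSINGNESS))
        elif row["maf"] < min_maf:
            report.removed_snps.append((snp, REASON_LOW_MAF))
        else:
            keep.append(snp)
    report.n_snps_after = len(keep)
    if not keep:
        logger.warning("all SNPs removed by QC")
    return G[keep], report


def filter_individuals(
    G: pd.DataFrame, max_missing: float = 0.10
) -> tuple[pd.DataFrame, QcReport]:
    """Drop individuals with a missing fraction strictly above ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise InvalidParameterError("threshold must lie in [0, 1]")
    frac = G.isna().mean(axis=1)
    bad = frac[frac > max_missing].index
    report = QcReport(
        n_snps_before=G.shape[1],
        n_snps_after=G.shape[1],
        n_individuals_before=G.shape[0],
        n_individuals_after=G.shape[0] - len(bad),
        removed_individuals=[(i, REASON_HIGH_MISSINGNESS) for i in bad],
    )
    if report.n_individuals_after == 0:
        logger.warning("all individuals removed by QC")
    return G.drop(index=bad), report


def apply_qc(
    G: pd.DataFrame,
    max_snp_missing: float = 0.10,
    min_maf: float = 0.01,
    max_individual_missing: float = 0.10,
    iterate: bool = False,
) -> tuple[pd.DataFrame, QcReport]:
    """SNP filters first (stats on the full individual set), then the
    individual filter on the SNP-filtered matrix; merged report.

    With ``iterate=True`` the two passes repeat until no further removal
    (off by default; the single pass is the documented contract).
    """
    validate_genotypes(G)
    total = QcReport(n_snps_before=G.shape[1], n_individuals_before=G.shape[0])
    current = G
    while True:
        current, snp_rep = filter_snps(current, max_snp_missing, min_maf)
        current, ind_rep = filter_individuals(current, max_individual_missing)
        total.removed_snps.extend(snp_rep.removed_snps)
        total.removed_individuals.extend(ind_rep.removed_individuals)
        if not iterate or (not snp_rep.removed_snps and not ind_rep.removed_individuals):
            break
    total.n_snps_after = current.shape[1]
    total.n_individuals_after = current.shape[0]
    logger.info(
        "QC: %d/%d SNPs and %d/%d individuals retained",
        total.n_snps_after, total.n_snps_before,
        total.n_individuals_after, total.n_individuals_before,
    )
    return current, total
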