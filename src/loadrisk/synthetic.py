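"""Synthetic case/control cohort generator.

Emulates the statistical structure the downstream analysis assumes,
without any external data: a liability-threshold disease model on top of
Hardy-Weinberg genotypes, an APOE diplotype risk gradient, clinical
covariate effects, MCAR genotype missingness, and deliberately planted
QC violations for round-trip testing.

The latent liability of an individual is

    L = w_score * Z + w_apoe * apoe_code + w_age * age_std
        + w_diabetes * diabetes + w_cholesterol * chol_std + eps

with Z the population-standardized raw weighted genetic score, age and
cholesterol standardized to their population moments, and
eps ~ Normal(0, noise_sd).  Individuals above the (1 - prevalence)
liability quantile of the source population are cases; the generator
draws source individuals until the requested class counts are reached.

Default weights were fixed once, by a coarse grid search during
development, so the default cohort reproduces the qualitative
effect-size structure of a late-onset Alzheimer's case/control sample:
genetic score and age with large standardized differences, a strong
APOE gradient, a modest diabetes association, a small negative
cholesterol difference, and null sex/smoking.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import features as ft
from .errors import InvalidParameterError, SimulationExhaustedError

#: theoretical moments used to standardize covariates inside the liability
_AGE_LOW, _AGE_HIGH = 60.0, 99.0
_AGE_MEAN = (_AGE_LOW + _AGE_HIGH) / 2.0
_AGE_SD = (_AGE_HIGH - _AGE_LOW) / np.sqrt(12.0)


@dataclass(frozen=True)
class SimParams:
    """Cohort-generator configuration.

    Counts default to a post-QC late-onset Alzheimer's cohort of 2547
    cases and 8699 controls (23:77) scored on 379 SNPs.  Liability
    weights are unitless multipliers of standardized predictors.
    """

    n_cases: int = 2547
    n_controls: int = 8699
    n_snps: int = 379
    maf_range: tuple[float, float] = (0.01, 0.5)
    beta_sd: float = 0.05
    w_score: float = 0.62
    w_apoe: float = 0.95
    w_age: float = 0.50
    w_diabetes: float = 0.60
    w_cholesterol: float = -0.10
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    prevalence: float = 0.23
    seed: int = 0
    apoe_allele_freqs: tuple[float, float, float] = (0.08, 0.78, 0.14)  # e2, e3, e4
    sex_prob: float = 0.5
    smoker_prob: float = 0.30
    diabetes_prob: float = 0.12
    cholesterol_mean: float = 5.7
    cholesterol_sd: float = 1.1

    def validate(self) -> "SimParams":
        if min(self.n_cases, self.n_controls, self.n_snps) <= 0:
            raise InvalidParameterError("counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidParameterError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidParameterError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.prevalence <= 1.0:
            raise InvalidParameterError("prevalence must lie in [0, 1]")
        weights = (self.w_score, self.w_apoe, self.w_age,
                   self.w_diabetes, self.w_cholesterol, self.noise_sd)
        if not all(np.isfinite(weights)):
            raise InvalidParameterError("weights must be finite")
        if abs(sum(self.apoe_allele_freqs) - 1.0) > 1e-9:
            raise InvalidParameterError("APOE allele frequencies must sum to 1")
        return self

    def null(self) -> "SimParams":
        """Copy with every liability weight zeroed (no-signal cohort)."""
        return replace(
            self, w_score=0.0, w_apoe=0.0, w_age=0.0,
            w_diabetes=0.0, w_cholesterol=0.0,
        )


@dataclass
class SimulatedCohort:
    """All tables share one individual-id set and order."""

    genotypes: pd.DataFrame
    apoe: pd.DataFrame
    phenotypes: pd.DataFrame
    true_liability: pd.Series
    stats: pd.DataFrame
    params: SimParams

    @property
    def labels(self) -> pd.Series:
        return (self.phenotypes["label"] == "case").astype(int)


def simulate_summary_stats(
    n_snps: int = 379,
    beta_sd: float = 0.05,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int = 0,
) -> pd.DataFrame:
    """GWAS-style summary statistics: unique SNP ids, an effect and other
    allele, a MAF uniform on ``maf_range`` and beta ~ Normal(0, beta_sd)."""
    if n_snps < 1:
        raise InvalidParameterError("n_snps must be >= 1")
    if beta_sd < 0:
        raise InvalidParameterError("beta_sd must be non-negative")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidParameterError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    width = len(str(n_snps))
    bases = np.array(list("ACGT"))
    eff = rng.integers(0, 4, size=n_snps)
    oth = (eff + rng.integers(1, 4, size=n_snps)) % 4
    return pd.DataFrame(
        {
            "snp_id": [f"snp{str(i + 1).zfill(width)}" for i in range(n_snps)],
            "effect_allele": bases[eff],
            "other_allele": bases[oth],
            "maf": rng.uniform(lo, hi, size=n_snps),
            "beta": rng.normal(0.0, beta_sd, size=n_snps),
        }
    )


def _draw_population(n: int, params: SimParams, stats: pd.DataFrame,
                     rng: np.random.Generator) -> dict:
    """One source-population batch of size n with liabilities."""
    mafs = stats["maf"].to_numpy()
    genotypes = rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
    G = pd.DataFrame(genotypes, columns=stats["snp_id"].to_numpy())

    # APOE: two haplotypes per individual under random mating
    freqs = np.asarray(params.apoe_allele_freqs)
    haps = rng.choice(3, size=(n, 2), p=freqs)  # 0=e2, 1=e3, 2=e4
    rs429358 = (haps == 2).sum(axis=1)          # C-count = number of e4
    rs7412 = 2 - (haps == 0).sum(axis=1)        # C-count = 2 - number of e2
    apoe_code = np.array(
        [ft.call_apoe_diplotype(a, b).ordinal_code for a, b in zip(rs429358, rs7412)]
    )

    age = rng.uniform(_AGE_LOW, _AGE_HIGH, size=n)
    sex = rng.binomial(1, params.sex_prob, size=n)
    smoker = rng.binomial(1, params.smoker_prob, size=n)
    diabetes = rng.binomial(1, params.diabetes_prob, size=n)
    chol = rng.normal(params.cholesterol_mean, params.cholesterol_sd, size=n)

    raw = ft.raw_weighted_scores(G, stats, missing_policy="zero").to_numpy()
    raw_sd = raw.std()
    z = (raw - raw.mean()) / raw_sd if raw_sd > 0 else np.zeros(n)

    liability = (
        params.w_score * z
        + params.w_apoe * apoe_code
        + params.w_age * (age - _AGE_MEAN) / _AGE_SD
        + params.w_diabetes * diabetes
        + params.w_cholesterol * (chol - params.cholesterol_mean) / params.cholesterol_sd
        + rng.normal(0.0, params.noise_sd, size=n)
    )
    return {
        "genotypes": genotypes, "rs429358": rs429358, "rs7412": rs7412,
        "age": age, "sex": sex, "smoker": smoker, "diabetes": diabetes,
        "cholesterol": chol, "liability": liability,
    }


def simulate_cohort(params: SimParams, stats: pd.DataFrame | None = None) -> SimulatedCohort:
    """Draw a case/control cohort under the liability-threshold model.

    Deterministic given ``params.seed``.  Raises
    :class:`SimulationExhaustedError` when the requested class counts
    cannot be reached (e.g. prevalence 0 with n_cases > 0).
    """
    params.validate()
    if stats is None:
        stats = simulate_summary_stats(
            params.n_snps, params.beta_sd, params.maf_range, seed=params.seed
        )
    if len(stats) != params.n_snps:
        raise InvalidParameterError(
            f"summary stats have {len(stats)} rows, expected {params.n_snps}"
        )
    rng = np.random.default_rng(params.seed)
    eps = 1e-12
    need_total = params.n_cases + params.n_controls
    n_draw = int(
        1.4 * max(
            params.n_cases / max(params.prevalence, eps),
            params.n_controls / max(1.0 - params.prevalence, eps),
        )
    ) + 50
    n_draw = min(n_draw, 200 * need_total + 1000)  # cap for extreme prevalence

    case_parts, control_parts = [], []
    n_cases_found = n_controls_found = 0
    for _attempt in range(30):
        pop = _draw_population(n_draw, params, stats, rng)
        cut = np.quantile(pop["liability"], 1.0 - params.prevalence)
        is_case = pop["liability"] > cut
        case_parts.append({k: v[is_case] for k, v in pop.items()})
        control_parts.append({k: v[~is_case] for k, v in pop.items()})
        n_cases_found += int(is_case.sum())
        n_controls_found += int((~is_case).sum())
        if n_cases_found >= params.n_cases and n_controls_found >= params.n_controls:
            break
    else:
        raise SimulationExhaustedError(
            f"could not reach {params.n_cases} cases / {params.n_controls} controls"
            f" (found {n_cases_found} / {n_controls_found})"
        )

    def take(parts, n):
        return {k: np.concatenate([p[k] for p in parts])[:n] for k in parts[0]}

    cases = take(case_parts, params.n_cases)
    controls = take(control_parts, params.n_controls)
    merged = {k: np.concatenate([cases[k], controls[k]]) for k in cases}
    labels = np.array(["case"] * params.n_cases + ["control"] * params.n_controls)

    # shuffle so case/control rows are interleaved
    order = rng.permutation(need_total)
    merged = {k: v[order] for k, v in merged.items()}
    labels = labels[order]

    ids = pd.Index(
        [f"ind{str(i + 1).zfill(len(str(need_total)))}" for i in range(need_total)],
        name="individual_id",
    )
    genotypes = pd.DataFrame(
        merged["genotypes"], index=ids, columns=stats["snp_id"].to_numpy()
    )
    if params.missing_rate > 0:
        genotypes = inject_missingness(
            genotypes, params.missing_rate, seed=int(rng.integers(2 ** 31))
        )
    apoe = pd.DataFrame(
        {"rs429358": merged["rs429358"], "rs7412": merged["rs7412"]}, index=ids
    )
    phenotypes = pd.DataFrame(
        {
            "label": labels,
            "age": merged["age"],
            "sex": merged["sex"],
            "smoker": merged["smoker"],
            "diabetes": merged["diabetes"],
            "cholesterol": merged["cholesterol"],
        },
        index=ids,
    )
    return SimulatedCohort(
        genotypes=genotypes,
        apoe=apoe,
        phenotypes=phenotypes,
        true_liability=pd.Series(merged["liability"], index=ids, name="liability"),
        stats=stats,
        params=params,
    )


def inject_missingness(G: pd.DataFrame, rate: float, seed: int = 0) -> pd.DataFrame:
    """Set each entry to missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise InvalidParameterError("rate must lie in [0, 1)")
    if rate == 0.0:
        return G.copy()
    rng = np.random.default_rng(seed)
    vals = G.to_numpy(dtype=float, copy=True)
    vals[rng.random(vals.shape) < rate] = np.nan
    return pd.DataFrame(vals, index=G.index, columns=G.columns)


def plant_qc_violations(
    G: pd.DataFrame,
    n_zero_variance: int = 0,
    n_low_maf: int = 0,
    n_high_missing_snps: int = 0,
    n_high_missing_individuals: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Overwrite random columns/rows with known QC violations.

    Returns ``(matrix, planted)`` where ``planted`` records the victim
    ids per violation type.  Low-MAF planting needs more than 50
    individuals so a single heterozygote sits below MAF 0.01; victim
    individuals get 20% missingness confined to non-victim SNP columns
    so the violations stay independent.
    """
    n_ind, n_snp = G.shape
    n_bad_snps = n_zero_variance + n_low_maf + n_high_missing_snps
    if n_bad_snps > n_snp or n_high_missing_individuals > n_ind:
        raise InvalidParameterError("requested violations exceed matrix dimensions")
    if n_low_maf > 0 and n_ind <= 50:
        raise InvalidParameterError(
            "low-MAF planting needs more than 50 individuals"
        )
    rng = np.random.default_rng(seed)
    vals = G.to_numpy(dtype=float, copy=True)
    snp_victims = rng.choice(n_snp, size=n_bad_snps, replace=False)
    zv = snp_victims[:n_zero_variance]
    lm = snp_victims[n_zero_variance : n_zero_variance + n_low_maf]
    hm = snp_victims[n_zero_variance + n_low_maf :]
    row_victims = rng.choice(n_ind, size=n_high_missing_individuals, replace=False)

    vals[:, zv] = 1.0  # constant column
    for j in lm:
        col = np.zeros(n_ind)
        n_alt = max(1, int(np.floor(0.005 * 2 * n_ind)))  # MAF < 0.01 strictly
        col[rng.choice(n_ind, size=n_alt, replace=False)] = 1.0
        vals[:, j] = col
    n_missing = int(np.ceil(0.2 * n_ind))
    for j in hm:
        col = rng.binomial(2, 0.3, size=n_ind).astype(float)
        col[:2] = (0.0, 1.0)  # keep variance after masking
        miss = rng.choice(np.arange(2, n_ind), size=n_missing, replace=False)
        col[miss] = np.nan
        vals[:, j] = col

    clean_cols = np.setdiff1d(np.arange(n_snp), snp_victims)
    n_row_missing = int(np.ceil(0.2 * len(clean_cols)))
    for i in row_victims:
        miss = rng.choice(clean_cols, size=n_row_missing, replace=False)
        vals[i, miss] = np.nan

    planted = {
        "zero_variance": [G.columns[j] for j in zv],
        "low_maf": [G.columns[j] for j in lm],
        "high_missing_snps": [G.columns[j] for j in hm],
        "high_missing_individuals": [G.index[i] for i in row_victims],
    }
    return pd.DataFrame(vals, index=G.index, columns=G.columns), planted


def clean_genotype_matrix(
    n_individuals: int, n_snps: int, maf: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """Hardy-Weinberg genotype matrix with no missingness (test substrate)."""
    rng = np.random.default_rng(seed)
    vals = rng.binomial(2, maf, size=(n_individuals, n_snps)).astype(float)
    ids = [f"ind{i + 1:04d}" for i in range(n_individuals)]
    snps = [f"snp{j + 1:04d}" for j in range(n_snps)]
    return pd.DataFrame(vals, index=pd.Index(ids, name="individual_id"), columns=snps)


def provenance_dict(params: SimParams, planted: dict | None = None) -> dict:
    """JSON-ready provenance record of a simulation."""
    d = {"params": asdict(params)}
    d["params"]["maf_range"] = list(params.maf_range)
    d["params"]["apoe_allele_freqs"] = list(params.apoe_allele_freqs)
    if planted is not None:
        d["planted"] = {k: list(map(str, v)) for k, v in planted.items()}
    return d


def write_provenance(path, params: SimParams, planted: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(provenance_dict(params, planted), fh, indent=2)
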