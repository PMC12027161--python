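"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as a TSV matrix (rows = individuals, columns =
SNP ids, values 0/1/2/NA counting effect alleles) or as a minimal
VCF 4.2 with one GT sample column per individual.  When a VCF is read
against summary statistics, each site's dosage is counted in the
summary-stats effect allele: sites whose REF/ALT pair is swapped
relative to A1/A2 are flipped, and irreconcilable allele pairs are
dropped with a log message.

Summary statistics use the conventional ``SNP / A1 / A2 / BETA`` TSV
header (A1 = effect allele); phenotypes are a TSV with columns
``individual_id, label, age, sex, smoker, diabetes, cholesterol``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TSV genotype matrix
# ---------------------------------------------------------------------------

def read_genotypes_tsv(path) -> pd.DataFrame:
    G = pd.read_csv(path, sep="\t", index_col=0)
    G.index = G.index.astype(str)
    G.index.name = "individual_id"
    return G.astype(float)

def write_genotypes_tsv(G: pd.DataFrame, path) -> None:
    G.to_csv(path, sep="\t", index_label="individual_id", na_rep="NA")


# ---------------------------------------------------------------------------
# summary statistics / phenotypes / APOE
# ---------------------------------------------------------------------------

_STATS_COLS = {"SNP": "snp_id", "A1": "effect_allele", "A2": "other_allele",
               "BETA": "beta"}


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_STATS_COLS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"summary stats missing columns {sorted(missing)}")
    out = df.rename(columns=_STATS_COLS)
    if "MAF" in df.columns:
        out = out.rename(columns={"MAF": "maf"})
    return out


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    out = stats.rename(columns={v: k for k, v in _STATS_COLS.items()})
    if "maf" in out.columns:
        out = out.rename(columns={"maf": "MAF"})
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="individual_id")
    df.index = df.index.astype(str)
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="individual_id", na_rep="NA")


def read_apoe_tsv(path) -> pd.DataFrame:
    """Three-column TSV: individual_id, rs429358, rs7412 (C-allele counts)."""
    df = pd.read_csv(path, sep="\t", index_col="individual_id")
    df.index = df.index.astype(str)
    return df[["rs429358", "rs7412"]].astype(int)


def write_apoe_tsv(apoe: pd.DataFrame, path) -> None:
    apoe.to_csv(path, sep="\t", index_label="individual_id")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    G: pd.DataFrame,
    stats: pd.DataFrame,
    path,
    chrom: str = "1",
) -> None:
    """Minimal VCF 4.2: one record per SNP, GT-only, REF = other allele,
    ALT = effect allele, so the ALT dosage equals the stored dosage."""
    stats = stats.set_index("snp_id")
    missing = [s for s in G.columns if s not in stats.index]
    if missing:
        raise InvalidParameterError(f"no alleles for SNPs {missing[:5]}")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in G.index)
            + "\n"
        )
        for pos, snp in enumerate(G.columns, start=1):
            ref = stats.loc[snp, "other_allele"]
            alt = stats.loc[snp, "effect_allele"]
            gts = "\t".join(
                "./." if np.isnan(d) else gt_map[float(d)] for d in G[snp]
            )
            fh.write(f"{chrom}\t{pos}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path, stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Effect-allele dosage matrix from a VCF.

    Without summary stats, dosage counts ALT alleles.  With stats, each
    site is reconciled against (effect_allele, other_allele): matching
    orientation counts ALT, swapped orientation flips (dosage 2 - alt
    count), anything else is dropped and logged.  ``./.`` becomes NaN.
    """
    from cyvcf2 import VCF

    by_snp = None
    if stats is not None:
        by_snp = stats.set_index("snp_id")[["effect_allele", "other_allele"]]

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for var in vcf:
        snp = var.ID
        if snp is None or len(var.ALT) != 1:
            logger.warning("skipping multi-allelic or unnamed site at %s:%s",
                           var.CHROM, var.POS)
            continue
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt (gts012), 3 unknown
        gt = np.asarray(var.gt_types, dtype=float)
        alt_count = np.where(gt == 3, np.nan, gt)
        if by_snp is None:
            columns[snp] = alt_count
            continue
        if snp not in by_snp.index:
            logger.info("site %s absent from summary stats; skipped", snp)
            continue
        a1, a2 = by_snp.loc[snp]
        if (var.REF, var.ALT[0]) == (a2, a1):
            columns[snp] = alt_count
        elif (var.REF, var.ALT[0]) == (a1, a2):
            columns[snp] = 2.0 - alt_count
        else:
            logger.warning(
                "site %s alleles %s/%s irreconcilable with %s/%s; dropped",
                snp, var.REF, var.ALT[0], a1, a2,
            )
    G = pd.DataFrame(columns, index=pd.Index(samples, name="individual_id"))
    return G


def read_genotypes(path, fmt: str | None = None,
                   stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Dispatch on format (``tsv`` or ``vcf``; inferred from the suffix)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    if fmt == "vcf":
        return read_genotypes_vcf(path, stats=stats)
    raise InvalidParameterError(f"unknown genotype format {fmt!r}")
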