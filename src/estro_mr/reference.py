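"""Published reference values for the oestrogen-receptor drug-target MR analysis.

This module packages, as plain data, the values printed in the published
analysis this package re-implements:

* the nine lead SNPs in *ESR1* / *ESR2* that proxy ERα and ERβ perturbation
  via positive-control biomarkers (bone mineral density, SHBG, haemoglobin),
  with their per-allele effects, standard errors and p-values;
* the annotated gene spans on genome build GRCh38.p14;
* the published two-sample MR estimates (beta, 95% CI, p, FDR-adjusted p) for
  the six neuropsychiatric / brain-structural outcomes.

The published instrument table prints neither genomic positions, other
alleles, nor allele frequencies. Positions below are therefore *synthetic*
placeholders placed inside the annotated gene spans (they only need to pass
the cis-region filter); other_allele and eaf are left missing, exactly as the
source prints them.
"""

from __future__ import annotations

import pandas as pd

from .summary_data import GeneRegion, VariantAssociation

__all__ = [
    "BMD",
    "SHBG",
    "HMG",
    "published_instruments",
    "gene_regions",
    "published_estimates",
    "RECEPTOR_BY_GENE",
]

# Biomarker (positive-control trait) labels used throughout the package.
BMD = "bone mineral density"
SHBG = "sex hormone-binding globulin levels"
HMG = "haemoglobin levels"

RECEPTOR_BY_GENE = {"ESR1": "ERalpha", "ESR2": "ERbeta"}

ESR1_REGION = GeneRegion(gene="ESR1", chrom="6", start=151_656_691, end=152_129_619)
ESR2_REGION = GeneRegion(gene="ESR2", chrom="14", start=64_084_232, end=64_338_112)


def gene_regions() -> list[GeneRegion]:
    """Annotated *ESR1* and *ESR2* spans (GRCh38.p14), default 200 kb flank."""
    return [ESR1_REGION, ESR2_REGION]


# (rsid, pos*, EA, beta, se, p, study, n, trait, gene)   * synthetic placeholder
_INSTRUMENT_ROWS = [
    ("rs2504069", 151_700_000, "C", -0.042, 0.002, 2.2e-82, "Morris (2019)", 426_824, BMD, "ESR1"),
    ("rs6905582", 151_760_000, "G", 0.057, 0.002, 2.7e-92, "Morris (2019)", 426_824, BMD, "ESR1"),
    ("rs2982573", 151_820_000, "T", -0.077, 0.002, 1.1e-305, "Morris (2019)", 426_824, BMD, "ESR1"),
    ("rs2234693", 151_880_000, "T", -0.017, 0.002, 1.8e-12, "Morris (2019)", 426_824, BMD, "ESR1"),
    ("rs10484920", 151_940_000, "A", 0.039, 0.004, 1.2e-18, "Kim (2018)", 394_929, BMD, "ESR1"),
    ("rs115192536", 152_000_000, "G", -0.053, 0.004, 6.4e-35, "Kim (2018)", 394_929, BMD, "ESR1"),
    ("rs547908752", 152_060_000, "C", 0.08, 0.007, 4.0e-27, "Kim (2018)", 394_929, BMD, "ESR1"),
    ("rs1738386", 152_110_000, "C", 0.020, 0.003, 1.5e-9, "Haas (2022)", 196_901, SHBG, "ESR1"),
    ("rs1256061", 64_200_000, "T", -0.021, 0.002, 1.6e-23, "Oskarsson (2020)", 684_122, HMG, "ESR2"),
]


def published_instruments() -> list[VariantAssociation]:
    """The nine instrument SNP records (7 BMD + 1 SHBG + 1 haemoglobin)."""
    records = []
    for rsid, pos, ea, beta, se, p, study, n, trait, gene in _INSTRUMENT_ROWS:
        chrom = "6" if gene == "ESR1" else "14"
        records.append(
            VariantAssociation(
                rsid=rsid,
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=None,
                beta=beta,
                se=se,
                p=p,
                eaf=None,
                trait=trait,
                study_id=study,
                n=n,
                ancestry="European",
                sex="combined",
            )
        )
    return records


# Published MR estimates: (instrument, receptor, outcome, method, n_snp,
# estimate, lci, uci, p, p_fdr-or-None). p_fdr is printed only for the
# primary (IVW / Wald ratio) rows, plus one weighted-median anxiety row.
_ESTIMATE_ROWS = [
    # ERalpha proxied by bone mineral density (multi-variant instrument)
    (BMD, "ERalpha", "AD", "ivw", 6, -0.079, -0.358, 0.199, 0.578, 0.693),
    (BMD, "ERalpha", "AD", "weighted_median", 6, -0.077, -0.400, 0.245, 0.638, None),
    (BMD, "ERalpha", "AD", "weighted_mode", 6, -0.077, -0.437, 0.283, 0.694, None),
    (BMD, "ERalpha", "AD", "simple_mode", 6, -0.128, -0.574, 0.318, 0.597, None),
    (BMD, "ERalpha", "AD", "mr_egger", 6, -0.021, -0.670, 0.629, 0.953, None),
    (BMD, "ERalpha", "Cortical GM volume", "ivw", 7, 0.171, 0.025, 0.317, 0.021, 0.096),
    (BMD, "ERalpha", "Cortical GM volume", "weighted_median", 7, 0.163, -0.011, 0.337, 0.066, None),
    (BMD, "ERalpha", "Cortical GM volume", "weighted_mode", 7, 0.176, -0.001, 0.353, 0.099, None),
    (BMD, "ERalpha", "Cortical GM volume", "simple_mode", 7, 0.195, -0.068, 0.458, 0.196, None),
    (BMD, "ERalpha", "Cortical GM volume", "mr_egger", 7, 0.112, -0.233, 0.456, 0.554, None),
    (BMD, "ERalpha", "HC volume", "ivw", 7, -0.192, -0.338, -0.046, 0.010, 0.089),
    (BMD, "ERalpha", "HC volume", "weighted_median", 7, -0.165, -0.346, 0.016, 0.075, None),
    (BMD, "ERalpha", "HC volume", "weighted_mode", 7, -0.171, -0.350, 0.008, 0.109, None),
    (BMD, "ERalpha", "HC volume", "simple_mode", 7, -0.249, -0.546, 0.047, 0.150, None),
    (BMD, "ERalpha", "HC volume", "mr_egger", 7, -0.323, -0.667, 0.022, 0.126, None),
    (BMD, "ERalpha", "WMH volume", "ivw", 7, 0.146, -0.064, 0.356, 0.172, 0.391),
    (BMD, "ERalpha", "WMH volume", "weighted_median", 7, 0.143, -0.029, 0.315, 0.104, None),
    (BMD, "ERalpha", "WMH volume", "weighted_mode", 7, 0.132, -0.055, 0.318, 0.216, None),
    (BMD, "ERalpha", "WMH volume", "simple_mode", 7, 0.196, -0.058, 0.450, 0.182, None),
    (BMD, "ERalpha", "WMH volume", "mr_egger", 7, 0.489, 0.060, 0.918, 0.076, None),
    (BMD, "ERalpha", "Depression", "ivw", 6, 0.060, -0.047, 0.166, 0.273, 0.400),
    (BMD, "ERalpha", "Depression", "weighted_median", 6, 0.055, -0.044, 0.155, 0.273, None),
    (BMD, "ERalpha", "Depression", "weighted_mode", 6, 0.047, -0.052, 0.147, 0.394, None),
    (BMD, "ERalpha", "Depression", "simple_mode", 6, 0.087, -0.086, 0.259, 0.371, None),
    (BMD, "ERalpha", "Depression", "mr_egger", 6, 0.106, -0.169, 0.381, 0.490, None),
    (BMD, "ERalpha", "Anxiety", "ivw", 6, 0.655, 0.107, 1.203, 0.019, 0.096),
    (BMD, "ERalpha", "Anxiety", "weighted_median", 6, 0.668, 0.081, 1.256, 0.026, None),
    (BMD, "ERalpha", "Anxiety", "weighted_mode", 6, 0.686, 0.008, 1.364, 0.104, None),
    (BMD, "ERalpha", "Anxiety", "simple_mode", 6, 0.251, -0.764, 1.267, 0.648, None),
    (BMD, "ERalpha", "Anxiety", "mr_egger", 6, 0.966, -0.300, 2.233, 0.209, None),
    # ERalpha proxied by SHBG (single-variant instrument)
    (SHBG, "ERalpha", "AD", "wald_ratio", 1, -0.005, -1.452, 1.442, 0.995, 0.995),
    (SHBG, "ERalpha", "Cortical GM volume", "wald_ratio", 1, 0.457, -0.330, 1.245, 0.255, 0.400),
    (SHBG, "ERalpha", "HC volume", "wald_ratio", 1, -0.547, -1.334, 0.241, 0.174, 0.391),
    (SHBG, "ERalpha", "WMH volume", "wald_ratio", 1, 0.433, -0.367, 1.233, 0.289, 0.400),
    (SHBG, "ERalpha", "Depression", "wald_ratio", 1, -0.271, -0.714, 0.172, 0.230, 0.400),
    (SHBG, "ERalpha", "Anxiety", "wald_ratio", 1, -1.889, -4.596, 0.819, 0.172, 0.391),
    # ERbeta proxied by haemoglobin (single-variant instrument; estimates
    # are inverse-coded — perturbation is proxied by *lower* haemoglobin)
    (HMG, "ERbeta", "AD", "wald_ratio", 1, 0.348, -0.773, 1.468, 0.543, 0.693),
    (HMG, "ERbeta", "Cortical GM volume", "wald_ratio", 1, -0.396, -1.006, 0.213, 0.203, 0.400),
    (HMG, "ERbeta", "HC volume", "wald_ratio", 1, 0.030, -0.580, 0.640, 0.924, 0.978),
    (HMG, "ERbeta", "WMH volume", "wald_ratio", 1, -0.547, -1.166, 0.072, 0.084, 0.301),
    (HMG, "ERbeta", "Depression", "wald_ratio", 1, -0.656, -0.992, -0.319, 0.001, 0.002),
    (HMG, "ERbeta", "Anxiety", "wald_ratio", 1, -0.444, -2.528, 1.640, 0.676, 0.761),
]


def published_estimates() -> pd.DataFrame:
    """Published MR estimates as a tidy frame.

    Columns: ``biomarker, receptor, outcome, method, n_snp, estimate, lci,
    uci, p, p_fdr`` (``p_fdr`` is NaN on sensitivity rows, mirroring the
    published tables, which adjust only the primary IVW / Wald-ratio family).
    """
    return pd.DataFrame(
        _ESTIMATE_ROWS,
        columns=[
            "biomarker",
            "receptor",
            "outcome",
            "method",
            "n_snp",
            "estimate",
            "lci",
            "uci",
            "p",
            "p_fdr",
        ],
    )
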