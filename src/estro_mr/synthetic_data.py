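"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the inputs of a cis drug-target MR study: a catalog
style candidate table of variant-biomarker associations (instrument rows plus
optional decoy rows failing each selection filter and optional LD "satellite"
rows that cluster with a main SNP), a matching outcome association table, a
block-structured LD matrix, and a truth record sufficient to score bias,
coverage, and pleiotropy recovery.

Data model, per instrument variant ``j``:

* true exposure effect ``b_j``: magnitude uniform on
  ``[0.4, 1.6] * beta_x_scale`` (defaults emulate the published instrument
  scale, |beta| 0.02–0.08, SE ~0.002);
* observed exposure effect ``beta_x_obs ~ Normal(b_j, se_x_j^2)``;
* per-variant pleiotropy ``alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd^2)``
  (directional when the mean is nonzero, balanced when only the SD is);
* observed outcome effect
  ``beta_y_obs ~ Normal(theta * b_j + alpha_j, se_y_j^2)``.

Reported exposure p-values are computed from the *latent* true effect rather
than the noisy observed beta, so every instrument row is genome-wide
significant by construction and the decoy guarantee (selection excludes
exactly the decoys) is exact. Identical config and seed reproduce the output
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .instrument_selection import STAGES
from .reference import BMD, ESR1_REGION, published_instruments
from .summary_data import GeneRegion, LDMatrix, VariantAssociation

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "SimulationTruth",
    "simulate_pair",
    "instrument_fixture",
    "selection_fixture",
    "study_shaped_inputs",
]

_NON_PALINDROMIC = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))
_PALINDROMIC = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated two-sample study.

    ``ld_cluster_spec`` lists ``(main_index, n_satellites, r2)`` blocks:
    satellite candidate rows correlated with the given instrument variant at
    the given r², designed to lose the main-SNP tie-break (single study,
    smaller sample).
    """

    n_snp: int = 7
    theta: float = 0.5
    beta_x_scale: float = 0.05
    se_x: float = 0.002
    se_y: float = 0.01
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    palindromic_fraction: float = 0.1
    n_decoy_per_filter: int = 0
    ld_cluster_spec: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0
    exposure_trait: str = BMD
    outcome_trait: str = "simulated outcome"
    n_exposure: int = 400_000
    n_outcome: int = 100_000

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValidationError("n_snp must be >= 1")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValidationError("sampling SE scales must be positive")
        if self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be non-negative")
        if not (0 <= self.palindromic_fraction <= 1):
            raise ValidationError("palindromic_fraction must be in [0, 1]")
        if self.n_decoy_per_filter < 0:
            raise ValidationError("n_decoy_per_filter must be non-negative")
        if self.beta_x_scale <= 0:
            raise ValidationError("beta_x_scale must be positive")
        for main_idx, n_sat, r2 in self.ld_cluster_spec:
            if not (0 <= main_idx < self.n_snp):
                raise ValidationError(f"ld_cluster_spec main index {main_idx} out of range")
            if n_sat < 1 or not (0 < r2 <= 1):
                raise ValidationError("ld_cluster_spec entries must have n>=1, r2 in (0,1]")


@dataclass(frozen=True)
class SimulationTruth:
    """Everything needed to score an analysis of the simulated study."""

    theta: float
    rsids: tuple[str, ...]
    beta_x_true: tuple[float, ...]
    alpha: tuple[float, ...]
    decoy_rsids: dict[str, tuple[str, ...]]
    satellite_rsids: tuple[str, ...]
    region: GeneRegion
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "beta_x_true": self.beta_x_true,
                "alpha": self.alpha,
                "theta": self.theta,
            }
        )


@dataclass(frozen=True)
class SimulatedStudy:
    exposure: tuple[VariantAssociation, ...]
    outcome: tuple[VariantAssociation, ...]
    ld: LDMatrix
    truth: SimulationTruth

    def __iter__(self):
        return iter((self.exposure, self.outcome, self.ld, self.truth))


def _survival_p(z: np.ndarray | float) -> np.ndarray:
    """Two-sided normal p with underflow clipped into (0, 1]."""
    return np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)


def simulate_pair(config: SimulationConfig) -> SimulatedStudy:
    """Generate one synthetic two-sample study from ``config``.

    Returns exposure candidates (instrument rows, then satellites, then
    decoys), outcome associations for the instrument rows, the LD matrix over
    all exposure rsIDs, and the truth record.
    """
    rng = np.random.default_rng(config.seed)
    region = ESR1_REGION
    L = config.n_snp

    b = config.beta_x_scale * rng.uniform(0.4, 1.6, L)
    se_x = config.se_x * rng.uniform(0.75, 1.25, L)
    se_y = config.se_y * rng.uniform(0.75, 1.25, L)
    beta_x_obs = b + rng.normal(0.0, 1.0, L) * se_x
    alpha = (
        rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, L)
        if config.pleiotropy_sd > 0
        else np.full(L, config.pleiotropy_mean)
    )
    beta_y_obs = config.theta * b + alpha + rng.normal(0.0, 1.0, L) * se_y

    rsids = tuple(f"rs{1_000_001 + j}" for j in range(L))
    span = region.end - region.start
    pos = region.start + ((np.arange(L) + 1) * span) // (L + 1)
    eaf = rng.uniform(0.05, 0.95, L)
    is_pal = rng.random(L) < config.palindromic_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC), L)
    nonpal_idx = rng.integers(0, len(_NON_PALINDROMIC), L)
    swap_outcome = rng.random(L) < 0.5

    p_exposure = _survival_p(b / se_x)
    p_outcome = _survival_p(beta_y_obs / se_y)

    exposure: list[VariantAssociation] = []
    outcome: list[VariantAssociation] = []
    for j in range(L):
        ea, oa = (_PALINDROMIC[pal_idx[j]] if is_pal[j] else _NON_PALINDROMIC[nonpal_idx[j]])
        exposure.append(
            VariantAssociation(
                rsid=rsids[j],
                chrom=region.chrom,
                pos=int(pos[j]),
                effect_allele=ea,
                other_allele=oa,
                beta=float(beta_x_obs[j]),
                se=float(se_x[j]),
                p=float(p_exposure[j]),
                eaf=float(eaf[j]),
                trait=config.exposure_trait,
                study_id="SIM-EXPOSURE",
                n=config.n_exposure,
                ancestry="European",
                sex="combined",
            )
        )
        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(beta_y_obs[j]), float(eaf[j])
        if swap_outcome[j]:
            o_ea, o_oa, o_beta, o_eaf = oa, ea, -o_beta, 1.0 - o_eaf
        outcome.append(
            VariantAssociation(
                rsid=rsids[j],
                chrom=region.chrom,
                pos=int(pos[j]),
                effect_allele=o_ea,
                other_allele=o_oa,
                beta=o_beta,
                se=float(se_y[j]),
                p=float(p_outcome[j]),
                eaf=o_eaf,
                trait=config.outcome_trait,
                study_id="SIM-OUTCOME",
                n=config.n_outcome,
                ancestry="European",
                sex="combined",
            )
        )

    satellites: list[VariantAssociation] = []
    sat_links: list[tuple[str, str, float]] = []  # (satellite, main, r2)
    counter = 0
    for main_idx, n_sat, r2 in config.ld_cluster_spec:
        for k in range(n_sat):
            counter += 1
            rsid = f"rs{2_000_000 + counter}"
            main = exposure[main_idx]
            satellites.append(
                replace(
                    main,
                    rsid=rsid,
                    pos=main.pos + 100 * (k + 1),
                    beta=float(main.beta * rng.uniform(0.8, 1.0)),
                    study_id="SIM-SATELLITE",
                    n=max(1, config.n_exposure // 8),
                )
            )
            sat_links.append((rsid, main.rsid, r2))

    decoys: list[VariantAssociation] = []
    decoy_rsids: dict[str, list[str]] = {s: [] for s in STAGES}
    template = dict(
        chrom=region.chrom,
        effect_allele="A",
        other_allele="G",
        beta=0.03,
        se=0.003,
        p=1e-20,
        eaf=0.3,
        trait=config.exposure_trait,
        study_id="SIM-DECOY",
        n=50_000,
        ancestry="European",
        sex="combined",
    )
    for k in range(config.n_decoy_per_filter):
        for stage, overrides in (
            ("significance", {"p": 1e-6}),
            ("region", {"pos": region.end + region.flank_bp + 10_000 * (k + 1)}),
            ("sex", {"sex": "male"}),
            ("ancestry", {"ancestry": "East Asian"}),
            ("biomarker", {"trait": "standing height"}),
        ):
            fields = {**template, "pos": int(region.start + 1000 * (k + 1)), **overrides}
            d = VariantAssociation(rsid=f"rs{3_000_000 + len(decoys) + 1}", **fields)
            decoys.append(d)
            decoy_rsids[stage].append(d.rsid)

    all_rows = exposure + satellites + decoys
    all_rsids = [r.rsid for r in all_rows]
    r2_matrix = np.eye(len(all_rsids))
    index = {r: i for i, r in enumerate(all_rsids)}
    # satellite blocks: satellite-main and satellite-satellite pairs share r2
    by_main: dict[str, list[str]] = {}
    for sat, main, r2 in sat_links:
        r2_matrix[index[sat], index[main]] = r2_matrix[index[main], index[sat]] = r2
        by_main.setdefault(main, []).append((sat, r2))
    for main, sats in by_main.items():
        for i in range(len(sats)):
            for j in range(i + 1, len(sats)):
                a, ra = sats[i]
                c, rc = sats[j]
                v = min(ra, rc)
                r2_matrix[index[a], index[c]] = r2_matrix[index[c], index[a]] = v

    truth = SimulationTruth(
        theta=config.theta,
        rsids=rsids,
        beta_x_true=tuple(float(x) for x in b),
        alpha=tuple(float(x) for x in alpha),
        decoy_rsids={s: tuple(v) for s, v in decoy_rsids.items()},
        satellite_rsids=tuple(s.rsid for s in satellites),
        region=region,
        config=config,
    )
    return SimulatedStudy(
        exposure=tuple(all_rows),
        outcome=tuple(outcome),
        ld=LDMatrix(all_rsids, r2_matrix),
        truth=truth,
    )


def instrument_fixture() -> list[VariantAssociation]:
    """The nine published instrument SNP records (7 BMD + 1 SHBG + 1 HMG)."""
    return published_instruments()


def selection_fixture():
    """Candidate pool emulating the catalog inputs behind the published instruments.

    Returns ``(candidates, regions, ld, config)`` such that
    :func:`~estro_mr.instrument_selection.build_instruments` yields three
    instruments sized 7 (bone mineral density), 1 (SHBG) and 1 (haemoglobin):
    the nine published records, a duplicate smaller-study row for rs2504069
    (largest-study dedup), an LD satellite of rs2234693 (main-SNP selection),
    and one decoy per selection filter.
    """
    from .instrument_selection import SelectionConfig
    from .reference import BMD, HMG, SHBG, gene_regions

    mains = published_instruments()
    regions = gene_regions()
    esr1 = regions[0]

    dup = replace(mains[0], study_id="Estrada (2012)", n=80_355, beta=-0.04, se=0.003, p=1e-20)
    satellite = replace(
        mains[3],  # rs2234693
        rsid="rs9340799",
        pos=mains[3].pos + 400,
        beta=-0.015,
        study_id="Kim (2018)",
        n=394_929,
    )
    decoys = [
        replace(mains[0], rsid="rs9990001", pos=esr1.start + 500, p=1e-6),
        replace(mains[0], rsid="rs9990002", pos=esr1.end + esr1.flank_bp + 50_000, p=1e-30),
        replace(mains[0], rsid="rs9990003", pos=esr1.start + 600, sex="male"),
        replace(mains[0], rsid="rs9990004", pos=esr1.start + 700, ancestry="East Asian"),
        replace(mains[0], rsid="rs9990005", pos=esr1.start + 800, trait="age at menarche"),
    ]
    candidates = mains + [dup, satellite] + decoys

    rsids = sorted({c.rsid for c in candidates})
    r2 = np.eye(len(rsids))
    idx = {r: i for i, r in enumerate(rsids)}
    r2[idx["rs2234693"], idx["rs9340799"]] = r2[idx["rs9340799"], idx["rs2234693"]] = 0.5
    ld = LDMatrix(rsids, r2)

    config = SelectionConfig(biomarker_allowlist=(BMD, SHBG, HMG))
    return candidates, regions, ld, config


STUDY_OUTCOMES = (
    "AD",
    "Cortical GM volume",
    "HC volume",
    "WMH volume",
    "Depression",
    "Anxiety",
)


def study_shaped_inputs(seed: int = 0, causal_effects: dict | None = None):
    """Instruments and synthetic outcome tables shaped like the published design.

    Builds the three instruments (7-variant bone-mineral-density, single-SNP
    SHBG, single-SNP haemoglobin) from the published records and simulates
    one outcome association table per study outcome under a null causal model
    by default (``causal_effects`` maps outcome label -> true theta to
    override). One BMD variant is omitted from the AD and Depression tables,
    mirroring the per-outcome instrument attrition of the published design
    (six of seven SNPs available for those outcomes).

    Returns ``(instruments, outcomes)`` with ``outcomes`` a dict of outcome
    label -> association rows.
    """
    from .instrument_selection import InstrumentSet
    from .reference import RECEPTOR_BY_GENE

    rng = np.random.default_rng(seed)
    causal_effects = causal_effects or {}
    records = published_instruments()
    by_trait: dict[str, list[VariantAssociation]] = {}
    for r in records:
        by_trait.setdefault(r.trait, []).append(r)
    instruments = [
        InstrumentSet(
            receptor=RECEPTOR_BY_GENE[rows[0].chrom == "14" and "ESR2" or "ESR1"],
            gene="ESR2" if rows[0].chrom == "14" else "ESR1",
            biomarker=trait,
            variants=tuple(sorted(rows, key=lambda v: v.rsid)),
        )
        for trait, rows in sorted(by_trait.items())
    ]

    # outcome-side SE scales loosely matching the published CI widths:
    # tight for the large depression GWAS, wide for the small anxiety one
    se_scale = {
        "AD": 0.03,
        "Cortical GM volume": 0.015,
        "HC volume": 0.015,
        "WMH volume": 0.02,
        "Depression": 0.007,
        "Anxiety": 0.05,
    }
    n_outcome = {
        "AD": 94_437,
        "Cortical GM volume": 22_138,
        "HC volume": 22_138,
        "WMH volume": 22_138,
        "Depression": 807_553,
        "Anxiety": 17_310,
    }
    drop_one = {"AD", "Depression"}  # these tables miss one BMD variant
    dropped_rsid = "rs547908752"

    outcomes: dict[str, list[VariantAssociation]] = {}
    alleles = {"A": "G", "C": "T", "G": "A", "T": "C"}
    for label in STUDY_OUTCOMES:
        theta = float(causal_effects.get(label, 0.0))
        rows = []
        for r in records:
            if label in drop_one and r.rsid == dropped_rsid:
                continue
            se = se_scale[label]
            beta = theta * r.beta + float(rng.normal(0.0, se))
            rows.append(
                VariantAssociation(
                    rsid=r.rsid,
                    chrom=r.chrom,
                    pos=r.pos,
                    effect_allele=r.effect_allele,
                    other_allele=alleles[r.effect_allele],
                    beta=beta,
                    se=se,
                    p=float(np.clip(2 * stats.norm.sf(abs(beta) / se), 1e-300, 1.0)),
                    eaf=float(rng.uniform(0.1, 0.9)),
                    trait=label,
                    study_id=f"SIM-{label}",
                    n=n_outcome[label],
                    ancestry="European",
                    sex="combined",
                )
            )
        outcomes[label] = rows
    return instruments, outcomes
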