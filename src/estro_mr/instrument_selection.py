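"""Candidate filtering and LD-based main-SNP selection for cis instruments.

The selection procedure mirrors drug-target MR practice: candidate
variant-biomarker associations (catalog-style rows, possibly several study
rows per SNP) are filtered sequentially on

1. genome-wide significance (p < 5e-8 by default),
2. position within the flanked gene region (±200 kb by default),
3. sex of the discovery sample (male-only rows removed),
4. genetic ancestry (European-only by default),
5. membership of the positive-control biomarker allowlist;

survivors are then clustered by linkage disequilibrium (connected components
of the graph with edges wherever r² >= 0.1, within a biomarker), and one
*main SNP* is chosen per cluster: first by whether the SNP was reported in
more than one study, then by the largest reporting study's sample size, then
by availability of summary statistics, with any residual tie broken by rsID
lexical order. Statistics for the chosen SNP come from its largest-n study.

A :class:`SelectionLedger` records per-stage exclusions so that
``initial == retained + sum(excluded)`` always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, DataError, ValidationError
from .summary_data import GeneRegion, LDMatrix, VariantAssociation, _norm_chrom

__all__ = [
    "SelectionConfig",
    "SelectionLedger",
    "InstrumentSet",
    "STAGES",
    "filter_candidates",
    "cluster_by_ld",
    "pick_main_snp",
    "build_instruments",
]

#: Filter stages, in ledger order.
STAGES = ("significance", "region", "sex", "ancestry", "biomarker")


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and label sets governing instrument selection."""

    biomarker_allowlist: tuple[str, ...]
    p_threshold: float = 5e-8
    flank_bp: int = 200_000
    allowed_ancestries: tuple[str, ...] = ("European",)
    excluded_sex: tuple[str, ...] = ("male",)
    ld_r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not self.biomarker_allowlist:
            raise ConfigurationError("biomarker allowlist must be non-empty")
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not (0 < self.ld_r2_threshold <= 1):
            raise ConfigurationError("ld_r2_threshold must be in (0, 1]")
        if self.flank_bp < 0:
            raise ConfigurationError("flank_bp must be non-negative")


@dataclass
class SelectionLedger:
    """Per-stage exclusion accounting for one selection run."""

    initial: int
    excluded: dict[str, list[tuple[str, str]]] = field(
        default_factory=lambda: {s: [] for s in STAGES}
    )
    retained: int = 0

    def record(self, stage: str, rsid: str, reason: str) -> None:
        self.excluded.setdefault(stage, []).append((rsid, reason))

    def counts(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.excluded.items()}

    @property
    def excluded_total(self) -> int:
        return sum(len(v) for v in self.excluded.values())

    def conserved(self) -> bool:
        return self.initial == self.retained + self.excluded_total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s, "excluded": len(v), "rsids": ";".join(r for r, _ in v)}
            for s, v in self.excluded.items()
        ]
        rows.append({"stage": "retained", "excluded": self.retained, "rsids": ""})
        return pd.DataFrame(rows)

    @staticmethod
    def merge(ledgers: Iterable["SelectionLedger"]) -> "SelectionLedger":
        merged = SelectionLedger(initial=0)
        for led in ledgers:
            merged.initial += led.initial
            merged.retained += led.retained
            for stage, items in led.excluded.items():
                merged.excluded.setdefault(stage, []).extend(items)
        return merged


@dataclass(frozen=True)
class InstrumentSet:
    """A biomarker-labelled set of mutually independent main SNPs."""

    receptor: str
    gene: str
    biomarker: str
    variants: tuple[VariantAssociation, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError(f"{self.gene}/{self.biomarker}: empty instrument")
        traits = {v.trait for v in self.variants}
        if traits != {self.biomarker}:
            raise ValidationError(
                f"{self.gene}: instrument variants carry traits {traits}, "
                f"expected {{{self.biomarker!r}}}"
            )

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(v.rsid for v in self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def validate_independent(self, ld: LDMatrix, r2_threshold: float) -> None:
        """Assert no retained pair reaches the clustering threshold."""
        rs = self.rsids
        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                r2 = ld.r2_between(rs[i], rs[j])
                if r2 >= r2_threshold:
                    raise ValidationError(
                        f"{rs[i]} and {rs[j]} have r2={r2} >= {r2_threshold}"
                    )


def filter_candidates(
    candidates: Sequence[VariantAssociation],
    region: GeneRegion,
    config: SelectionConfig,
) -> tuple[list[VariantAssociation], SelectionLedger]:
    """Apply the five selection filters in ledger order.

    Returns surviving rows (order preserved) and the exclusion ledger. Each
    row is excluded at the *first* stage it fails, so stage counts depend on
    the fixed order while the surviving set does not.
    """
    ledger = SelectionLedger(initial=len(candidates))
    survivors: list[VariantAssociation] = []
    allow = set(config.biomarker_allowlist)
    ancestries = set(config.allowed_ancestries)
    excluded_sex = set(config.excluded_sex)
    for c in candidates:
        if not (c.p < config.p_threshold):
            ledger.record("significance", c.rsid, f"p={c.p:.3g} >= {config.p_threshold:g}")
        elif not region.contains(c.chrom, c.pos, flank_bp=config.flank_bp):
            ledger.record("region", c.rsid, f"pos {c.chrom}:{c.pos} outside flanked region")
        elif c.sex in excluded_sex:
            ledger.record("sex", c.rsid, f"sex label {c.sex!r} excluded")
        elif c.ancestry not in ancestries:
            ledger.record("ancestry", c.rsid, f"ancestry {c.ancestry!r} not allowed")
        elif c.trait not in allow:
            ledger.record("biomarker", c.rsid, f"trait {c.trait!r} not in allowlist")
        else:
            survivors.append(c)
    ledger.retained = len(survivors)
    return survivors, ledger


def cluster_by_ld(
    survivors: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float,
) -> list[list[str]]:
    """Connected components of the r²-graph, within each biomarker.

    Edges join rsIDs of the *same* trait with r² >= ``r2_threshold``;
    singletons form their own cluster. Clusters are returned sorted by their
    lexicographically smallest member so output never depends on input order.
    """
    by_trait: dict[str, list[str]] = {}
    seen: set[str] = set()
    for s in survivors:
        if s.rsid not in ld:
            raise DataError(f"survivor {s.rsid} absent from LD matrix")
        if (s.trait, s.rsid) not in seen:
            seen.add((s.trait, s.rsid))
            by_trait.setdefault(s.trait, []).append(s.rsid)
    clusters: list[list[str]] = []
    for trait in sorted(by_trait):
        rsids = sorted(by_trait[trait])
        g = nx.Graph()
        g.add_nodes_from(rsids)
        for i in range(len(rsids)):
            for j in range(i + 1, len(rsids)):
                if ld.r2_between(rsids[i], rsids[j]) >= r2_threshold:
                    g.add_edge(rsids[i], rsids[j])
        clusters.extend(sorted(c) for c in nx.connected_components(g))
    clusters.sort(key=lambda c: c[0])
    return clusters


def pick_main_snp(
    cluster: Sequence[str],
    all_reports: Sequence[VariantAssociation],
    available: set[str] | None = None,
) -> VariantAssociation:
    """Choose the main SNP of an LD cluster.

    Ranking key, lexicographic: (reported in more than one study, largest
    reporting-study sample size, summary statistics available), residual ties
    broken by rsID lexical order. The returned record is the chosen rsID's
    largest-n study row.

    ``available`` optionally names the rsIDs with retrievable full summary
    statistics; by default all are assumed available.
    """
    if not cluster:
        raise ValidationError("cannot pick a main SNP from an empty cluster")
    reports_by_rsid: dict[str, list[VariantAssociation]] = {}
    for r in all_reports:
        reports_by_rsid.setdefault(r.rsid, []).append(r)

    def key(rsid: str):
        rows = reports_by_rsid.get(rsid)
        if not rows:
            raise DataError(f"no association rows for cluster member {rsid}")
        multi_study = len({r.study_id for r in rows}) > 1
        max_n = max(r.n for r in rows)
        avail = True if available is None else rsid in available
        return (multi_study, max_n, avail)

    ranked = sorted(cluster, key=lambda r: (key(r), _ReversedStr(r)), reverse=True)
    chosen = ranked[0]
    rows = reports_by_rsid[chosen]
    return max(rows, key=lambda r: (r.n, _ReversedStr(r.study_id)))


class _ReversedStr(str):
    """String with inverted ordering, so ``reverse=True`` sorts keep the
    lexicographically *smallest* rsID first on residual ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def build_instruments(
    candidates: Sequence[VariantAssociation],
    regions: Sequence[GeneRegion],
    ld: LDMatrix,
    config: SelectionConfig,
    receptor_by_gene: Mapping[str, str] | None = None,
) -> tuple[list[InstrumentSet], SelectionLedger]:
    """Full selection: filter per gene region, prune by LD, pick main SNPs.

    Candidates are routed to the region sharing their chromosome; rows on a
    chromosome with no region are counted as region-stage exclusions. One
    :class:`InstrumentSet` is produced per (gene, biomarker) with at least
    one surviving variant; variants are sorted by rsID for determinism.
    """
    from .reference import RECEPTOR_BY_GENE

    receptors = dict(RECEPTOR_BY_GENE)
    if receptor_by_gene:
        receptors.update(receptor_by_gene)

    by_chrom: dict[str, GeneRegion] = {}
    for region in regions:
        key = _norm_chrom(region.chrom)
        if key in by_chrom:
            raise ConfigurationError(
                f"regions {by_chrom[key].gene} and {region.gene} share chromosome {key}; "
                "supply them in separate runs"
            )
        by_chrom[key] = region

    routed: dict[str, list[VariantAssociation]] = {k: [] for k in by_chrom}
    orphan_ledger = SelectionLedger(initial=0)
    for c in candidates:
        key = _norm_chrom(c.chrom)
        if key in routed:
            routed[key].append(c)
        else:
            orphan_ledger.initial += 1
            orphan_ledger.record("region", c.rsid, f"chromosome {c.chrom} matches no region")

    instruments: list[InstrumentSet] = []
    ledgers = [orphan_ledger]
    for key, region in by_chrom.items():
        survivors, ledger = filter_candidates(routed[key], region, config)
        ledgers.append(ledger)
        by_trait: dict[str, list[VariantAssociation]] = {}
        for s in survivors:
            by_trait.setdefault(s.trait, []).append(s)
        for trait in sorted(by_trait):
            rows = by_trait[trait]
            clusters = cluster_by_ld(rows, ld, config.ld_r2_threshold)
            mains = [pick_main_snp(cluster, rows) for cluster in clusters]
            mains.sort(key=lambda v: v.rsid)
            instruments.append(
                InstrumentSet(
                    receptor=receptors.get(region.gene, region.gene),
                    gene=region.gene,
                    biomarker=trait,
                    variants=tuple(mains),
                )
            )
    instruments.sort(key=lambda ins: (ins.gene, ins.biomarker))
    return instruments, SelectionLedger.merge(ledgers)
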