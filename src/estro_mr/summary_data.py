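"""Domain types and tabular I/O for summary-level GWAS association evidence.

Every other module consumes the types defined here: a
:class:`VariantAssociation` is one variant-trait association row (the unit of
both exposure and outcome evidence in two-sample MR), a :class:`GeneRegion`
delimits the cis window around a drug-target gene, and an :class:`LDMatrix`
holds precomputed pairwise squared allelic correlations.

On-disk formats are plain TSV with a header row:

* association tables: columns ``rsid, chrom, pos, effect_allele,
  other_allele, beta, se, pval, eaf, trait, study_id, n, ancestry, sex``;
  the missing-value token is ``NA`` (``other_allele`` and ``eaf`` are the
  only optional fields — catalog-style sources frequently omit both);
* LD matrices: square TSV whose header row and first column are rsIDs.

Coordinates are 1-based inclusive (GWAS Catalog convention); region
membership is ``start - flank <= pos <= end + flank``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "VariantAssociation",
    "GeneRegion",
    "LDMatrix",
    "read_associations",
    "write_associations",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_regions",
    "write_regions",
    "ASSOCIATION_COLUMNS",
    "MISSING_TOKEN",
]

MISSING_TOKEN = "NA"

ASSOCIATION_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "eaf",
    "trait",
    "study_id",
    "n",
    "ancestry",
    "sex",
)

#: Columns a source file must provide; ``other_allele`` and ``eaf`` may be absent.
MANDATORY_COLUMNS = tuple(
    c for c in ASSOCIATION_COLUMNS if c not in ("other_allele", "eaf")
)

#: Default column dialect: canonical name -> file header name.
DEFAULT_DIALECT: Mapping[str, str] = {c: c for c in ASSOCIATION_COLUMNS}

VALID_SEX_LABELS = ("female", "male", "combined")

#: Genome build the packaged gene coordinates refer to.
GENOME_BUILD = "GRCh38.p14"


def _norm_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class VariantAssociation:
    """One variant-trait association from a GWAS summary table.

    ``beta`` is the additive effect per copy of ``effect_allele`` in the
    trait's units (SD units for quantitative biomarkers, log-odds for binary
    outcomes); ``se`` its standard error; ``eaf`` the effect-allele frequency.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str | None
    beta: float
    se: float
    p: float
    eaf: float | None
    trait: str
    study_id: str
    n: int
    ancestry: str
    sex: str

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if not (isinstance(self.pos, (int, np.integer)) and self.pos >= 1):
            raise ValidationError(f"{self.rsid}: pos must be a 1-based integer, got {self.pos!r}")
        if not self.effect_allele:
            raise ValidationError(f"{self.rsid}: effect_allele must be non-empty")
        if self.other_allele is not None and self.other_allele == self.effect_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not (math.isfinite(self.beta) and math.isfinite(self.se)):
            raise ValidationError(f"{self.rsid}: beta and se must be finite")
        if self.se <= 0:
            raise ValidationError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0 < self.p <= 1):
            raise ValidationError(f"{self.rsid}: p must be in (0, 1], got {self.p}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.rsid}: eaf must be in (0, 1), got {self.eaf}")
        if self.n < 1:
            raise ValidationError(f"{self.rsid}: sample size must be >= 1, got {self.n}")
        if self.sex not in VALID_SEX_LABELS:
            raise ValidationError(
                f"{self.rsid}: sex must be one of {VALID_SEX_LABELS}, got {self.sex!r}"
            )

    @property
    def allele_pair(self) -> frozenset[str]:
        """Unordered allele pair; singleton set when other_allele is unknown."""
        if self.other_allele is None:
            return frozenset((self.effect_allele,))
        return frozenset((self.effect_allele, self.other_allele))


@dataclass(frozen=True)
class GeneRegion:
    """A gene span with a symmetric cis flank (default 200 kb on each side)."""

    gene: str
    chrom: str
    start: int
    end: int
    flank_bp: int = 200_000
    build: str = GENOME_BUILD

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene}: start must be <= end")
        if self.flank_bp < 0:
            raise ValidationError(f"{self.gene}: flank_bp must be non-negative")

    def contains(self, chrom: str, pos: int, flank_bp: int | None = None) -> bool:
        """Inclusive window test: ``start - flank <= pos <= end + flank``."""
        flank = self.flank_bp if flank_bp is None else flank_bp
        if _norm_chrom(chrom) != _norm_chrom(self.chrom):
            return False
        return self.start - flank <= pos <= self.end + flank


class LDMatrix:
    """A labelled symmetric matrix of pairwise r² values with unit diagonal."""

    def __init__(self, rsids: Sequence[str], r2: np.ndarray):
        rsids = tuple(rsids)
        r2 = np.asarray(r2, dtype=float)
        if r2.ndim != 2 or r2.shape[0] != r2.shape[1]:
            raise FormatError(f"LD matrix must be square, got shape {r2.shape}")
        if len(rsids) != r2.shape[0]:
            raise FormatError("rsid labels do not match matrix dimension")
        if len(set(rsids)) != len(rsids):
            raise ValidationError("duplicate rsIDs in LD matrix labels")
        if np.any(r2 < -1e-12) or np.any(r2 > 1 + 1e-12):
            raise ValidationError("LD matrix entries must lie in [0, 1]")
        if np.max(np.abs(r2 - r2.T)) > 1e-6:
            raise ValidationError("LD matrix asymmetric beyond tolerance 1e-6")
        if np.max(np.abs(np.diag(r2) - 1.0)) > 1e-6:
            raise ValidationError("LD matrix diagonal must be 1")
        r2 = np.clip((r2 + r2.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(r2, 1.0)
        self.rsids = rsids
        self.r2 = r2
        self._index = {r: i for i, r in enumerate(rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def __len__(self) -> int:
        return len(self.rsids)

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def subset(self, rsids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[r] for r in rsids]
        return LDMatrix(rsids, self.r2[np.ix_(idx, idx)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LDMatrix)
            and self.rsids == other.rsids
            and np.array_equal(self.r2, other.r2)
        )


def _parse_float(value: str, column: str, optional: bool = False) -> float | None:
    if value == MISSING_TOKEN or value == "":
        if optional:
            return None
        raise ValidationError(f"missing value in mandatory column {column!r}")
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(f"non-numeric {column}: {value!r}") from exc


def _parse_int(value: str, column: str) -> int:
    if value == MISSING_TOKEN or value == "":
        raise ValidationError(f"missing value in mandatory column {column!r}")
    try:
        return int(float(value))
    except ValueError as exc:
        raise ValidationError(f"non-integer {column}: {value!r}") from exc


def read_associations(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[VariantAssociation]:
    """Read a TSV association table into validated records.

    ``dialect`` maps canonical column names to the file's header names and is
    merged over the shipped GWAS-Catalog-style default, so callers only name
    the columns that differ. Rows violating type invariants are rejected
    collectively with row-indexed diagnostics — never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canonical in MANDATORY_COLUMNS:
        if colmap[canonical] not in df.columns:
            raise FormatError(f"missing mandatory column {colmap[canonical]!r}")

    def cell(row, canonical: str) -> str:
        name = colmap[canonical]
        return str(row[name]).strip() if name in df.columns else MISSING_TOKEN

    records: list[VariantAssociation] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            other = cell(row, "other_allele")
            eaf = _parse_float(cell(row, "eaf"), "eaf", optional=True)
            rec = VariantAssociation(
                rsid=cell(row, "rsid"),
                chrom=cell(row, "chrom"),
                pos=_parse_int(cell(row, "pos"), "pos"),
                effect_allele=cell(row, "effect_allele"),
                other_allele=None if other in (MISSING_TOKEN, "") else other,
                beta=_parse_float(cell(row, "beta"), "beta"),
                se=_parse_float(cell(row, "se"), "se"),
                p=_parse_float(cell(row, "pval"), "pval"),
                eaf=eaf,
                trait=cell(row, "trait"),
                study_id=cell(row, "study_id"),
                n=_parse_int(cell(row, "n"), "n"),
                ancestry=cell(row, "ancestry"),
                sex=cell(row, "sex"),
            )
            records.append(rec)
        except ValidationError as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row(s) in {path.name}:\n" + "\n".join(problems)
        )
    return records


def write_associations(records: Sequence[VariantAssociation], path: str | Path) -> Path:
    """Write records to TSV. Round-trip identity with :func:`read_associations`."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "rsid": r.rsid,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": MISSING_TOKEN if r.other_allele is None else r.other_allele,
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pval": repr(r.p),
                "eaf": MISSING_TOKEN if r.eaf is None else repr(r.eaf),
                "trait": r.trait,
                "study_id": r.study_id,
                "n": r.n,
                "ancestry": r.ancestry,
                "sex": r.sex,
            }
        )
    df = pd.DataFrame(rows, columns=list(ASSOCIATION_COLUMNS)).rename(
        columns={"pval": "pval"}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square labelled r² matrix; validates symmetry, range and diagonal."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"LD matrix in {path.name} is not square: {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"row and column rsID labels differ in {path.name}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric LD entry in {path.name}: {exc}") from exc
    return LDMatrix([str(r) for r in df.index], values)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(ld.r2, index=list(ld.rsids), columns=list(ld.rsids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )
    return path


REGION_COLUMNS = ("gene", "chrom", "start", "end", "flank_bp")


def read_regions(path: str | Path) -> list[GeneRegion]:
    """Read gene regions from TSV (columns gene, chrom, start, end[, flank_bp])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    regions = []
    for _, row in df.iterrows():
        flank = row.get("flank_bp", "")
        regions.append(
            GeneRegion(
                gene=row["gene"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                flank_bp=int(flank) if flank not in ("", MISSING_TOKEN) else 200_000,
            )
        )
    return regions


def write_regions(regions: Sequence[GeneRegion], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {"gene": g.gene, "chrom": g.chrom, "start": g.start, "end": g.end, "flank_bp": g.flank_bp}
            for g in regions
        ],
        columns=list(REGION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)
    return path
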