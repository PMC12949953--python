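"""Allele harmonisation of exposure and outcome summary statistics.

Two-sample MR requires the variant-exposure and variant-outcome effects to
refer to the same allele. For each instrument variant:

* absent from the outcome table -> ``dropped_missing`` (no proxy lookup);
* outcome effect allele equals the exposure effect allele -> kept as-is;
* outcome effect allele equals the exposure *other* allele -> kept with the
  outcome beta negated (``flipped=True``);
* non-palindromic variants reported on the opposite strand are resolved by
  base complement before the same matching;
* palindromic variants (A/T or C/G, strand unresolvable from alleles) are
  aligned by effect-allele-frequency concordance when both sides carry an
  informative frequency, and dropped otherwise (``dropped_palindromic``).
  A frequency is *informative* when it lies outside the ambiguity window
  ``|eaf - 0.5| < window`` (default 0.08).

Exposure records from catalog-style sources often print no other allele. In
that case a variant is alignable only if the outcome allele pair contains the
exposure effect allele, read at face value on the reported strand; strand
complements are never guessed and such unalignable variants are excluded
with a reason (``dropped_incompatible``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .instrument_selection import InstrumentSet
from .summary_data import VariantAssociation

__all__ = [
    "HarmonisedPair",
    "harmonise",
    "analysis_ready",
    "STATUS_KEPT",
    "STATUS_MISSING",
    "STATUS_PALINDROMIC",
    "STATUS_INCOMPATIBLE",
]

logger = logging.getLogger(__name__)

STATUS_KEPT = "kept"
STATUS_MISSING = "dropped_missing"
STATUS_PALINDROMIC = "dropped_palindromic"
STATUS_INCOMPATIBLE = "dropped_incompatible"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = (frozenset(("A", "T")), frozenset(("C", "G")))


@dataclass(frozen=True)
class HarmonisedPair:
    """One variant's aligned exposure/outcome effect pair."""

    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    flipped: bool
    palindromic: bool
    status: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status == STATUS_KEPT:
            if not (self.se_exposure > 0 and self.se_outcome > 0):
                raise ValueError(f"{self.rsid}: kept pair must have positive SEs")


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        return None


def _is_palindromic(pair: frozenset[str]) -> bool:
    return pair in _PALINDROMIC_PAIRS


def _informative(eaf: float | None, window: float) -> bool:
    return eaf is not None and abs(eaf - 0.5) >= window


def harmonise(
    exposure: InstrumentSet | Sequence[VariantAssociation],
    outcome_assocs: Sequence[VariantAssociation],
    palindromic_eaf_window: float = 0.08,
) -> list[HarmonisedPair]:
    """Align outcome effects to each instrument variant's effect allele.

    Returns one :class:`HarmonisedPair` per instrument variant, in instrument
    order, with a status explaining any exclusion. When several outcome rows
    share an rsID the largest-n row is used.
    """
    variants = exposure.variants if isinstance(exposure, InstrumentSet) else tuple(exposure)
    outcome_by_rsid: dict[str, VariantAssociation] = {}
    for o in outcome_assocs:
        cur = outcome_by_rsid.get(o.rsid)
        if cur is None or o.n > cur.n:
            outcome_by_rsid[o.rsid] = o

    pairs: list[HarmonisedPair] = []
    for v in variants:
        o = outcome_by_rsid.get(v.rsid)
        if o is None:
            pairs.append(
                HarmonisedPair(
                    rsid=v.rsid,
                    beta_exposure=v.beta,
                    se_exposure=v.se,
                    beta_outcome=float("nan"),
                    se_outcome=float("nan"),
                    flipped=False,
                    palindromic=False,
                    status=STATUS_MISSING,
                    reason="variant absent from outcome associations",
                )
            )
            continue
        pairs.append(_harmonise_one(v, o, palindromic_eaf_window))
    return pairs


def _make(v, o, flipped, palindromic, status, reason=""):
    return HarmonisedPair(
        rsid=v.rsid,
        beta_exposure=v.beta,
        se_exposure=v.se,
        beta_outcome=(-o.beta if flipped else o.beta) if status == STATUS_KEPT else float("nan"),
        se_outcome=o.se if status == STATUS_KEPT else float("nan"),
        flipped=flipped,
        palindromic=palindromic,
        status=status,
        reason=reason,
    )


def _harmonise_one(
    v: VariantAssociation, o: VariantAssociation, window: float
) -> HarmonisedPair:
    exp_ea = v.effect_allele.upper()
    exp_oa = v.other_allele.upper() if v.other_allele else None
    out_ea = o.effect_allele.upper()
    out_oa = o.other_allele.upper() if o.other_allele else None
    out_pair = frozenset(a for a in (out_ea, out_oa) if a)

    # Exposure other allele unknown: match by containment on the reported
    # strand; never guess strand via complement.
    if exp_oa is None:
        palindromic = len(out_pair) == 2 and _is_palindromic(out_pair)
        if out_ea == exp_ea:
            return _make(v, o, False, palindromic, STATUS_KEPT)
        if out_oa == exp_ea:
            return _make(v, o, True, palindromic, STATUS_KEPT)
        return _make(
            v, o, False, palindromic, STATUS_INCOMPATIBLE,
            "exposure other allele unknown and outcome alleles "
            f"{sorted(out_pair)} do not contain {exp_ea}",
        )

    exp_pair = frozenset((exp_ea, exp_oa))
    palindromic = _is_palindromic(exp_pair)

    if palindromic:
        # Strand is unresolvable from alleles; require informative, mutually
        # consistent allele frequencies on both sides.
        if out_pair not in (exp_pair,):
            return _make(
                v, o, False, True, STATUS_INCOMPATIBLE,
                f"palindromic exposure pair {sorted(exp_pair)} vs outcome {sorted(out_pair)}",
            )
        if not (_informative(v.eaf, window) and _informative(o.eaf, window)):
            return _make(
                v, o, False, True, STATUS_PALINDROMIC,
                "allele frequency missing or within ambiguity window",
            )
        # Frequency concordance decides orientation: the printed letters are
        # uninformative for a palindromic pair, so the outcome effect allele
        # corresponds to the exposure effect allele iff both frequencies fall
        # on the same side of 0.5.
        same_side = (v.eaf - 0.5) * (o.eaf - 0.5) > 0
        return _make(v, o, not same_side, True, STATUS_KEPT)

    # Non-palindromic: direct match, then strand-complement match.
    for ea, oa, via_complement in (
        (exp_ea, exp_oa, False),
        (_complement(exp_ea), _complement(exp_oa), True),
    ):
        if ea is None or oa is None:
            continue
        if out_ea == ea and (out_oa is None or out_oa == oa):
            return _make(v, o, False, False, STATUS_KEPT)
        if out_ea == oa and (out_oa is None or out_oa == ea):
            return _make(v, o, True, False, STATUS_KEPT)
    return _make(
        v, o, False, False, STATUS_INCOMPATIBLE,
        f"outcome alleles {sorted(out_pair)} neither match nor complement "
        f"exposure pair {sorted(exp_pair)}",
    )


def analysis_ready(pairs: Sequence[HarmonisedPair]) -> list[HarmonisedPair]:
    """Filter to kept pairs, preserving order; log the drop summary."""
    kept = [p for p in pairs if p.status == STATUS_KEPT]
    dropped = len(pairs) - len(kept)
    if dropped:
        by_status: dict[str, int] = {}
        for p in pairs:
            if p.status != STATUS_KEPT:
                by_status[p.status] = by_status.get(p.status, 0) + 1
        logger.info("harmonisation dropped %d/%d variants: %s", dropped, len(pairs), by_status)
    if not kept:
        logger.warning("no harmonised variants kept (all %d dropped)", len(pairs))
    return kept
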