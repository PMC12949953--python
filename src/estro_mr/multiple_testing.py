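"""Benjamini–Hochberg FDR adjustment across the primary MR estimates.

The correction family contains exactly the primary-method rows — one IVW or
Wald-ratio estimate per (instrument, outcome) cell; sensitivity analyses
(Egger, median, modes) are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["TestFamily", "bh_adjust", "family_from_results", "PRIMARY_METHODS"]

PRIMARY_METHODS = ("ivw", "wald_ratio")


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{k >= i} p_(k) * n / k``, capped at 1.
    """
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot adjust an empty p-value list")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(arr, alpha=0.05, method="fdr_bh")[1]


@dataclass(frozen=True)
class TestFamily:
    """Labelled raw p-values with their BH-adjusted q-values."""

    labels: tuple[str, ...]
    p: tuple[float, ...]
    q: tuple[float, ...]

    @classmethod
    def from_pvalues(cls, labels: Sequence[str], pvals: Sequence[float]) -> "TestFamily":
        if len(labels) != len(pvals):
            raise ValidationError("labels and p-values must have equal length")
        q = bh_adjust(pvals)
        return cls(tuple(labels), tuple(float(p) for p in pvals), tuple(float(x) for x in q))

    def __len__(self) -> int:
        return len(self.p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "p": self.p, "q": self.q})


def family_from_results(
    results: pd.DataFrame, primary_methods: Sequence[str] = PRIMARY_METHODS
) -> TestFamily:
    """Build the correction family from a results table.

    ``results`` needs columns ``method`` and ``p``; rows whose method is a
    primary method (IVW or Wald ratio) form the family. Labels combine the
    ``instrument`` and ``outcome`` columns when present.
    """
    if "method" not in results.columns or "p" not in results.columns:
        raise ValidationError("results must have 'method' and 'p' columns")
    primary = results[results["method"].isin(primary_methods)]
    if primary.empty:
        raise ValidationError("no primary (IVW / Wald ratio) rows to correct")
    if {"instrument", "outcome"} <= set(primary.columns):
        labels = [
            f"{row.instrument}|{row.outcome}" for row in primary.itertuples(index=False)
        ]
    else:
        labels = [str(i) for i in primary.index]
    return TestFamily.from_pvalues(labels, primary["p"].tolist())
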