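"""Orchestration: harmonise -> estimate -> FDR for a full analysis plan.

An :class:`AnalysisPlan` names the instruments (receptor, gene, biomarker,
exposure source), the outcomes, estimator settings, and an optional follow-up
rule: for any (instrument, outcome) cell significant after FDR, a standard
biomarker-on-outcome MR is run with a supplied genome-wide biomarker
instrument, probing whether the positive-control biomarker itself drives the
outcome (an exclusion-restriction check).

Estimator routing per cell: one harmonised variant -> Wald ratio only;
two or more -> IVW (primary) plus, where at least three variants remain,
weighted median, weighted and simple mode, and MR-Egger (slope and
intercept). BH-adjusted q-values are appended to the primary rows only.

Instruments whose biomarker proxies receptor perturbation *inversely* (e.g.
lower haemoglobin for ERβ agonism) carry a display-layer sign-flip flag in
the forest export; stored estimates are never modified.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, EmptyInstrumentError
from .harmonisation import analysis_ready, harmonise
from .instrument_selection import InstrumentSet
from .mr_estimators import MREstimate, ivw, mode_estimate, mr_egger, wald_ratio, weighted_median
from .multiple_testing import PRIMARY_METHODS, family_from_results
from .summary_data import VariantAssociation, read_associations

__all__ = [
    "AnalysisSettings",
    "AnalysisPlan",
    "ResultsBundle",
    "analyse",
    "run_pipeline",
    "render_tables",
    "load_plan",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisSettings:
    """Estimator and correction settings shared across all cells."""

    seed: int = 0
    n_boot: int = 1000
    effects_model: str = "multiplicative_random"
    palindromic_eaf_window: float = 0.08
    bandwidth_factor: float = 1.0
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha < 1):
            raise ConfigurationError("fdr_alpha must be in (0, 1)")


@dataclass(frozen=True)
class InstrumentSource:
    receptor: str
    gene: str
    biomarker: str
    path: str
    inverse_coded: bool = False


@dataclass(frozen=True)
class AnalysisPlan:
    """File-backed description of a full analysis."""

    instruments: tuple[InstrumentSource, ...]
    outcomes: tuple[tuple[str, str], ...]  # (label, path)
    settings: AnalysisSettings = AnalysisSettings()
    follow_up: tuple[tuple[str, str], ...] = ()  # (biomarker, instrument path)

    def __post_init__(self) -> None:
        labels = [i.biomarker for i in self.instruments]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("instrument biomarkers must be unique in a plan")
        out_labels = [label for label, _ in self.outcomes]
        if len(set(out_labels)) != len(out_labels):
            raise ConfigurationError("outcome labels must be unique in a plan")


@dataclass
class ResultsBundle:
    results: pd.DataFrame
    forest: pd.DataFrame
    harmonisation_log: pd.DataFrame
    follow_up: pd.DataFrame
    failures: list[dict]
    provenance: dict


RESULT_COLUMNS = [
    "instrument",
    "receptor",
    "gene",
    "biomarker",
    "outcome",
    "analysis",
    "method",
    "n_snp",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "p",
    "q",
]


def _estimate_rows(pairs, settings: AnalysisSettings, cell_seed: int) -> list[MREstimate]:
    """Route estimators by instrument size."""
    L = len(pairs)
    if L == 1:
        return [wald_ratio(pairs[0])]
    rows = [ivw(pairs, effects_model=settings.effects_model)]
    if L >= 3:
        rows.append(weighted_median(pairs, n_boot=settings.n_boot, seed=cell_seed))
        rows.append(
            mode_estimate(
                pairs, "weighted", settings.bandwidth_factor, settings.n_boot, cell_seed + 1
            )
        )
        rows.append(
            mode_estimate(
                pairs, "simple", settings.bandwidth_factor, settings.n_boot, cell_seed + 2
            )
        )
        slope, intercept = mr_egger(pairs)
        rows.extend([slope, intercept])
    return rows


def analyse(
    instruments: Sequence[InstrumentSet],
    outcomes: Mapping[str, Sequence[VariantAssociation]],
    settings: AnalysisSettings = AnalysisSettings(),
    inverse_coded: Mapping[str, bool] | None = None,
    follow_up_instruments: Mapping[str, InstrumentSet] | None = None,
) -> ResultsBundle:
    """Run every (instrument, outcome) cell and append BH q-values.

    ``outcomes`` maps outcome label -> outcome association rows.
    ``inverse_coded`` maps instrument biomarker -> display-flip flag.
    ``follow_up_instruments`` maps biomarker -> a genome-wide biomarker
    instrument used for the follow-up biomarker-on-outcome MR of cells
    significant after FDR.
    """
    inverse_coded = dict(inverse_coded or {})
    rows: list[dict] = []
    log_rows: list[dict] = []
    failures: list[dict] = []
    cell_index = 0
    for ins in instruments:
        label = ins.biomarker
        for outcome_label, outcome_rows in outcomes.items():
            cell_index += 1
            pairs = harmonise(ins, outcome_rows, settings.palindromic_eaf_window)
            kept = analysis_ready(pairs)
            log_rows.append(
                {
                    "instrument": label,
                    "outcome": outcome_label,
                    "n_instrument": len(ins),
                    "n_kept": len(kept),
                    "n_dropped_missing": sum(p.status == "dropped_missing" for p in pairs),
                    "n_dropped_palindromic": sum(p.status == "dropped_palindromic" for p in pairs),
                    "n_dropped_incompatible": sum(p.status == "dropped_incompatible" for p in pairs),
                }
            )
            if not kept:
                failures.append(
                    {
                        "stage": "harmonisation",
                        "instrument": label,
                        "outcome": outcome_label,
                        "error": "no harmonised variants kept",
                    }
                )
                continue
            try:
                estimates = _estimate_rows(kept, settings, settings.seed + 97 * cell_index)
            except Exception as exc:  # pragma: no cover - defensive manifest path
                failures.append(
                    {
                        "stage": "estimation",
                        "instrument": label,
                        "outcome": outcome_label,
                        "error": str(exc),
                    }
                )
                continue
            for est in estimates:
                rows.append(
                    {
                        "instrument": label,
                        "receptor": ins.receptor,
                        "gene": ins.gene,
                        "biomarker": ins.biomarker,
                        "outcome": outcome_label,
                        "analysis": "primary",
                        "method": est.method,
                        "n_snp": est.n_snp,
                        "beta": est.beta,
                        "se": est.se,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "p": est.p,
                        "q": np.nan,
                    }
                )

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not results.empty:
        primary_mask = results["method"].isin(PRIMARY_METHODS)
        if primary_mask.any():
            family = family_from_results(results)
            results.loc[primary_mask, "q"] = list(family.q)
    forest = _forest_frame(results, inverse_coded)

    follow_rows: list[dict] = []
    if follow_up_instruments:
        significant = results[
            results["method"].isin(PRIMARY_METHODS) & (results["q"] <= settings.fdr_alpha)
        ]
        for row in significant.itertuples(index=False):
            fu = follow_up_instruments.get(row.biomarker)
            if fu is None:
                continue
            pairs = harmonise(fu, outcomes[row.outcome], settings.palindromic_eaf_window)
            kept = analysis_ready(pairs)
            if not kept:
                failures.append(
                    {
                        "stage": "follow_up",
                        "instrument": row.biomarker,
                        "outcome": row.outcome,
                        "error": "no harmonised variants kept",
                    }
                )
                continue
            for est in _estimate_rows(kept, settings, settings.seed + 1_000_003):
                follow_rows.append(
                    {
                        "instrument": row.biomarker,
                        "receptor": "",
                        "gene": "",
                        "biomarker": row.biomarker,
                        "outcome": row.outcome,
                        "analysis": "follow_up",
                        "method": est.method,
                        "n_snp": est.n_snp,
                        "beta": est.beta,
                        "se": est.se,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "p": est.p,
                        "q": np.nan,
                    }
                )
    follow_up = pd.DataFrame(follow_rows, columns=RESULT_COLUMNS)

    return ResultsBundle(
        results=results,
        forest=forest,
        harmonisation_log=pd.DataFrame(log_rows),
        follow_up=follow_up,
        failures=failures,
        provenance={"seed": settings.seed, "version": __version__},
    )


def _forest_frame(results: pd.DataFrame, inverse_coded: Mapping[str, bool]) -> pd.DataFrame:
    """Primary rows only, with a display-layer sign-flip flag for instruments
    whose biomarker proxies perturbation inversely. Stored estimates untouched."""
    primary = results[results["method"].isin(PRIMARY_METHODS)].copy()
    if primary.empty:
        return pd.DataFrame(
            columns=["instrument", "outcome", "method", "beta", "ci_low", "ci_high", "display_flip"]
        )
    primary["display_flip"] = primary["biomarker"].map(
        lambda b: bool(inverse_coded.get(b, False))
    )
    return primary[
        ["instrument", "outcome", "method", "beta", "ci_low", "ci_high", "q", "display_flip"]
    ].reset_index(drop=True)


METHOD_DISPLAY = {
    "ivw": "IVW",
    "wald_ratio": "Wald ratio",
    "weighted_median": "Weighted median",
    "weighted_mode": "Weighted mode",
    "simple_mode": "Simple mode",
    "mr_egger": "MR Egger",
    "egger_intercept": "MR Egger intercept",
}

_TABLE_METHOD_ORDER = [
    "ivw",
    "wald_ratio",
    "weighted_median",
    "weighted_mode",
    "simple_mode",
    "mr_egger",
]


def render_tables(bundle: ResultsBundle, out_dir: str | Path) -> list[Path]:
    """Write one published-layout TSV per instrument.

    Columns Outcome, Method, SNPs, Estimate, LCI, UCI, p, p_FDR; numbers to 3
    decimals; p_FDR blank on sensitivity rows (only primary estimates are
    FDR-corrected). Egger intercept diagnostics stay in the results bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    df = bundle.results
    for instrument in df["instrument"].unique():
        sub = df[(df["instrument"] == instrument) & (df["method"] != "egger_intercept")].copy()
        sub["_m"] = sub["method"].map(_TABLE_METHOD_ORDER.index)
        sub = sub.sort_values(["outcome", "_m"], kind="stable")
        rows = []
        for r in sub.itertuples(index=False):
            rows.append(
                {
                    "Outcome": r.outcome,
                    "Method": METHOD_DISPLAY[r.method],
                    "SNPs": r.n_snp,
                    "Estimate": f"{r.beta:.3f}",
                    "LCI": f"{r.ci_low:.3f}",
                    "UCI": f"{r.ci_high:.3f}",
                    "p": f"{r.p:.3f}",
                    "p_FDR": "" if pd.isna(r.q) else f"{r.q:.3f}",
                }
            )
        slug = instrument.lower().replace(" ", "_").replace("-", "_")
        path = out_dir / f"estimates_{slug}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def load_plan(path: str | Path) -> AnalysisPlan:
    """Read an analysis plan from YAML (paths resolved relative to the file)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    settings = AnalysisSettings(**raw.get("settings", {}))
    instruments = tuple(
        InstrumentSource(
            receptor=i["receptor"],
            gene=i["gene"],
            biomarker=i["biomarker"],
            path=resolve(i["path"]),
            inverse_coded=bool(i.get("inverse_coded", False)),
        )
        for i in raw["instruments"]
    )
    outcomes = tuple((o["label"], resolve(o["path"])) for o in raw["outcomes"])
    follow_up = tuple(
        (f["biomarker"], resolve(f["path"])) for f in raw.get("follow_up", [])
    )
    return AnalysisPlan(
        instruments=instruments, outcomes=outcomes, settings=settings, follow_up=follow_up
    )


def run_pipeline(plan: AnalysisPlan, out_dir: str | Path) -> ResultsBundle:
    """Execute a plan end to end and write all outputs under ``out_dir``.

    Writes ``results.tsv``, ``forest.tsv``, ``harmonisation_log.tsv``,
    per-instrument rendered tables, ``follow_up.tsv`` when triggered, a
    ``failures.json`` manifest when any cell failed (partial results are
    still written), and a ``provenance.json`` audit block.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    instruments = []
    inverse_coded = {}
    for src in plan.instruments:
        records = read_associations(src.path)
        variants = tuple(sorted((r for r in records if r.trait == src.biomarker), key=lambda r: r.rsid))
        if not variants:
            raise EmptyInstrumentError(
                f"no rows with trait {src.biomarker!r} in {src.path}"
            )
        instruments.append(
            InstrumentSet(
                receptor=src.receptor, gene=src.gene, biomarker=src.biomarker, variants=variants
            )
        )
        inverse_coded[src.biomarker] = src.inverse_coded

    outcomes = {label: read_associations(p) for label, p in plan.outcomes}
    follow_up_instruments = {}
    for biomarker, p in plan.follow_up:
        records = read_associations(p)
        follow_up_instruments[biomarker] = InstrumentSet(
            receptor="", gene="", biomarker=biomarker,
            variants=tuple(sorted(records, key=lambda r: r.rsid)),
        )

    bundle = analyse(
        instruments,
        outcomes,
        settings=plan.settings,
        inverse_coded=inverse_coded,
        follow_up_instruments=follow_up_instruments or None,
    )

    bundle.results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    bundle.forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False)
    bundle.harmonisation_log.to_csv(out_dir / "harmonisation_log.tsv", sep="\t", index=False)
    if not bundle.follow_up.empty:
        bundle.follow_up.to_csv(out_dir / "follow_up.tsv", sep="\t", index=False)
    render_tables(bundle, out_dir)
    if bundle.failures:
        (out_dir / "failures.json").write_text(json.dumps(bundle.failures, indent=2))

    plan_digest = hashlib.sha256(
        json.dumps(
            {
                "instruments": [vars(i) for i in plan.instruments],
                "outcomes": list(plan.outcomes),
                "follow_up": list(plan.follow_up),
                "settings": vars(plan.settings),
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()
    bundle.provenance = {
        "seed": plan.settings.seed,
        "version": __version__,
        "plan_sha256": plan_digest,
    }
    (out_dir / "provenance.json").write_text(json.dumps(bundle.provenance, indent=2, sort_keys=True))
    logger.info(
        "pipeline complete: %d result rows, %d failures", len(bundle.results), len(bundle.failures)
    )
    return bundle
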