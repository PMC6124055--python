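"""End-to-end study orchestration and machine-readable reports.

``run_study1`` evaluates a policy's effect on a coded article corpus:
descriptive cascade counts, proportion CIs, chi-squared tests, the
segmented logistic ITS fit with risk-ratio effects and the trend
decomposition, and the binned time series behind the trajectory figure.
``run_study2`` runs the reproducibility audit: value-level classification
at both assistance stages, article-level outcomes with simultaneous CIs,
and the error/issue tallies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

from . import audit as audit_mod
from . import corpus as corpus_mod
from . import its as its_mod
from .audit import (
    ArticleOutcome,
    Classification,
    Stage,
    classify_article,
    classify_value,
    tally_issue_loci,
    tally_value_errors,
)
from .corpus import CascadeSummary, CodingTable, TimeBin
from .its import EffectEstimate, ITSFit, TrendDecomposition
from .proportions import (
    BinomialCI,
    ChiSquareResult,
    MultinomialCI,
    pearson_chi2_2x2,
    sison_glaz_intervals,
    wilson_cc_interval,
)

__all__ = ["Study1Report", "Study2Report", "run_study1", "run_study2", "write_report"]

logger = logging.getLogger("odpeval")


@dataclass(frozen=True)
class Study1Report:
    n_articles: int
    cascade: CascadeSummary
    das_ci_pre: BinomialCI
    das_ci_post: BinomialCI
    chi2_das: ChiSquareResult
    chi2_reusable: ChiSquareResult
    its_fit: ITSFit
    effects: list[EffectEstimate]
    decomposition: TrendDecomposition | None
    binned_series: list[TimeBin]
    reusability_its: dict | None = None


@dataclass(frozen=True)
class Study2Report:
    n_values: int
    n_articles: int
    value_tally_before: pd.DataFrame
    value_tally_final: pd.DataFrame
    error_counts_final: dict[str, int]
    article_outcomes: dict[str, int]
    outcome_cis: MultinomialCI
    initial_error_ci: BinomialCI
    major_rate_ci: BinomialCI
    issue_tally: pd.DataFrame


def _study1_from_table(table: CodingTable, reusability_block: bool = True) -> Study1Report:
    cascade = corpus_mod.summarize_cascade(table)
    pre, post = cascade.pre, cascade.post

    # Fit first: an empty or single-class period surfaces as a separation
    # error rather than a degenerate contingency table downstream.
    fit = its_mod.fit_its(table, outcome="das")
    effects = its_mod.estimate_effects(fit)

    chi2_das = pearson_chi2_2x2(
        [
            [pre.n_das, pre.n_articles - pre.n_das],
            [post.n_das, post.n_articles - post.n_das],
        ]
    )
    chi2_reusable = pearson_chi2_2x2(
        [
            [pre.n_reusable, pre.n_articles - pre.n_reusable],
            [post.n_reusable, post.n_articles - post.n_reusable],
        ]
    )
    try:
        decomposition = its_mod.decompose_trend(fit)
    except ValueError as exc:
        logger.warning("trend decomposition unavailable: %s", exc)
        decomposition = None

    reus_block = None
    if reusability_block:
        try:
            reus_fit = its_mod.fit_its(table, outcome="reusable")
            reus_block = {
                "fit": reus_fit,
                "effects": its_mod.estimate_effects(reus_fit),
            }
        except (its_mod.SeparationError, its_mod.ConvergenceError) as exc:
            logger.warning("reusability ITS unavailable: %s", exc)

    return Study1Report(
        n_articles=len(table),
        cascade=cascade,
        das_ci_pre=wilson_cc_interval(pre.n_das, pre.n_articles),
        das_ci_post=wilson_cc_interval(post.n_das, post.n_articles),
        chi2_das=chi2_das,
        chi2_reusable=chi2_reusable,
        its_fit=fit,
        effects=effects,
        decomposition=decomposition,
        binned_series=corpus_mod.bin_time_series(table, bin_width=50, outcome="das"),
        reusability_its=reus_block,
    )


def run_study1(
    coding_csv: str | Path, policy_date: date, reusability_block: bool = True
) -> Study1Report:
    """Load a coding table and produce the full policy-evaluation report."""
    table = corpus_mod.read_coding_table(coding_csv, policy_date)
    return _study1_from_table(table, reusability_block=reusability_block)


def run_study1_from_table(table: CodingTable, **kwargs) -> Study1Report:
    return _study1_from_table(table, **kwargs)


def run_study2(audit_csv: str | Path, issues_csv: str | Path) -> Study2Report:
    """Load audit tables and produce the reproducibility report."""
    records = audit_mod.read_audit_table(audit_csv)
    issues = audit_mod.read_issue_table(issues_csv)
    return run_study2_from_records(records, issues)


def run_study2_from_records(records, issues) -> Study2Report:
    by_article: dict[str, list] = {}
    for r in records:
        by_article.setdefault(r.article_id, []).append(r)

    before = [classify_value(r, Stage.BEFORE_ASSISTANCE) for r in records]
    final = [classify_value(r, r.final_stage()) for r in records]
    outcomes = [classify_article(rs) for rs in by_article.values()]

    outcome_counts = {o.value: 0 for o in ArticleOutcome}
    for o in outcomes:
        outcome_counts[o.outcome.value] += 1

    error_counts = {c.value: 0 for c in Classification}
    for a in final:
        error_counts[a.classification.value] += 1

    n_articles = len(by_article)
    # Articles with a blocking error before assistance, i.e. those whose
    # initial reproducibility check failed (minor discrepancies alone do
    # not fail a check).
    n_initial_errors = sum(
        any(a.classification in audit_mod.BLOCKING for a in before if a.article_id == aid)
        for aid in by_article
    )
    n_major = error_counts[Classification.MAJOR_NUMERICAL.value]

    # Three-category outcome split: reproducible without assistance /
    # with assistance / not fully reproducible (with or without).
    three_way = (
        outcome_counts[ArticleOutcome.REPRODUCIBLE.value],
        outcome_counts[ArticleOutcome.REPRODUCIBLE_WITH_ASSISTANCE.value],
        outcome_counts[ArticleOutcome.NOT_FULLY_REPRODUCIBLE.value]
        + outcome_counts[ArticleOutcome.NOT_FULLY_REPRODUCIBLE_DESPITE_ASSISTANCE.value],
    )

    return Study2Report(
        n_values=len(records),
        n_articles=n_articles,
        value_tally_before=tally_value_errors(before),
        value_tally_final=tally_value_errors(final),
        error_counts_final=error_counts,
        article_outcomes=outcome_counts,
        outcome_cis=sison_glaz_intervals(three_way),
        initial_error_ci=wilson_cc_interval(n_initial_errors, n_articles),
        major_rate_ci=wilson_cc_interval(n_major, len(records)),
        issue_tally=tally_issue_loci(issues),
    )


def _to_jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return {
            "index": list(obj.index),
            "columns": list(obj.columns),
            "data": [
                [None if isinstance(v, float) and math.isnan(v) else v for v in row]
                for row in obj.itertuples(index=False)
            ],
        }
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, date):
        return obj.isoformat()
    if hasattr(obj, "value") and hasattr(type(obj), "__members__"):  # Enum
        return obj.value
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize a report losslessly.

    ``json`` writes one file with full-precision numbers (display rounding
    is a presentation concern, not a storage one); ``csv_bundle`` writes
    the tabular members as individual CSV files next to a JSON manifest.
    """
    path = Path(path)
    payload = _to_jsonable(report)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    elif format == "csv_bundle":
        path.mkdir(parents=True, exist_ok=True)
        tables = {}
        for f in dataclasses.fields(report):
            value = getattr(report, f.name)
            if isinstance(value, pd.DataFrame):
                out = path / f"{f.name}.csv"
                value.to_csv(out)
                tables[f.name] = out.name
                payload.pop(f.name, None)
        payload["_tables"] = tables
        (path / "report.json").write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")
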