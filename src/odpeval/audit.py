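"""Analytic-reproducibility audit engine.

Each *target value* is one statistic printed in an article (a mean, a test
statistic, a p-value, ...) that a reanalysis of the shared data attempted
to re-obtain, first independently ("before assistance") and, where the
original authors were contacted, again afterwards.  Discrepancies are
quantified by percentage error

    PE = |obtained - reported| / |reported| * 100,

after rounding the obtained value to the reported value's printed
precision.  A PE in (0, 10) is a minor numerical error, PE >= 10 a major
numerical error.  p-values are special-cased: a re-obtained p on the
opposite side of the 0.05 significance boundary is a decision error,
whatever the PE.  A value whose analysis specification was too ambiguous
or incomplete to attempt is an insufficient-information error.

Articles are classified from their values at the final stage: any
remaining insufficient-information, major or decision error makes the
article not fully reproducible; otherwise it is reproducible, with a
flag for whether author assistance was needed to get there.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ValueType",
    "Classification",
    "Stage",
    "ArticleOutcome",
    "IssueLocus",
    "INSUFFICIENT",
    "UNATTEMPTED",
    "TargetValueRecord",
    "ValueAssessment",
    "ArticleAuditOutcome",
    "IssueRecord",
    "percentage_error",
    "classify_value",
    "classify_article",
    "tally_value_errors",
    "tally_issue_loci",
    "read_audit_table",
    "write_audit_table",
    "read_issue_table",
    "write_issue_table",
]


class ValueType(enum.Enum):
    COUNT_PROPORTION = "count_proportion"
    CONFIDENCE_INTERVAL = "confidence_interval"
    MEAN_MEDIAN = "mean_median"
    DEGREES_OF_FREEDOM = "degrees_of_freedom"
    EFFECT_SIZE = "effect_size"
    TEST_STATISTIC = "test_statistic"
    P_VALUE = "p_value"
    SD_SE = "sd_se"
    MISC = "misc"


class Classification(enum.Enum):
    MATCH = "match"
    MINOR_NUMERICAL = "minor_numerical"
    MAJOR_NUMERICAL = "major_numerical"
    DECISION_ERROR = "decision_error"
    INSUFFICIENT_INFORMATION = "insufficient_information"


#: Classifications that block article-level reproducibility.
BLOCKING = frozenset(
    {
        Classification.MAJOR_NUMERICAL,
        Classification.DECISION_ERROR,
        Classification.INSUFFICIENT_INFORMATION,
    }
)


class Stage(enum.Enum):
    BEFORE_ASSISTANCE = "before_assistance"
    AFTER_ASSISTANCE = "after_assistance"


class ArticleOutcome(enum.Enum):
    REPRODUCIBLE = "reproducible"
    REPRODUCIBLE_WITH_ASSISTANCE = "reproducible_with_assistance"
    NOT_FULLY_REPRODUCIBLE = "not_fully_reproducible"
    NOT_FULLY_REPRODUCIBLE_DESPITE_ASSISTANCE = (
        "not_fully_reproducible_despite_assistance"
    )


class IssueLocus(enum.Enum):
    TYPOGRAPHICAL = "typographical"
    ANALYSIS_UNDERSPECIFIED = "analysis_underspecified"
    ORIGINAL_ANALYSIS_ISSUE = "original_analysis_issue"
    DATA_FILE_ISSUE = "data_file_issue"
    UNIDENTIFIED = "unidentified"


# Sentinel flags for the obtained-value slots.
INSUFFICIENT = "insufficient"
UNATTEMPTED = "unattempted"

_P_BOUNDARY = 0.05


def _parse_reported(raw: str) -> tuple[float, int, str | None]:
    """Parse a printed value into (value, decimals, inequality prefix)."""
    raw = raw.strip()
    ineq = None
    body = raw
    if raw[:1] in ("<", ">"):
        ineq = raw[0]
        body = raw[1:].strip()
    value = float(body)
    if "e" in body.lower():
        decimals = 0  # scientific notation: compare as-is
    elif "." in body:
        decimals = len(body.split(".")[1])
    else:
        decimals = 0
    return value, decimals, ineq


@dataclass(frozen=True)
class TargetValueRecord:
    """One reported statistic and its re-obtained counterpart(s).

    ``reported_raw`` preserves the printed form ("12.30", "<0.001", ...);
    the numeric value, its printed decimal places and any inequality
    prefix are derived from it.  ``obtained_before`` / ``obtained_after``
    hold a float or one of the string flags :data:`INSUFFICIENT` /
    :data:`UNATTEMPTED`; ``obtained_after`` is only present when author
    assistance was requested.
    """

    article_id: str
    value_type: ValueType
    reported_raw: str
    obtained_before: float | str
    obtained_after: float | str | None = None
    assistance_requested: bool = False

    def __post_init__(self) -> None:
        _parse_reported(self.reported_raw)  # raises on garbage
        if self.obtained_after is not None and not self.assistance_requested:
            raise ValueError(
                f"article {self.article_id!r}: obtained_after present "
                "without assistance_requested"
            )
        for name in ("obtained_before", "obtained_after"):
            v = getattr(self, name)
            if isinstance(v, str) and v not in (INSUFFICIENT, UNATTEMPTED):
                raise ValueError(f"{name}={v!r} is neither a number nor a known flag")

    @property
    def reported_value(self) -> float:
        return _parse_reported(self.reported_raw)[0]

    @property
    def reported_decimals(self) -> int:
        return _parse_reported(self.reported_raw)[1]

    @property
    def inequality(self) -> str | None:
        return _parse_reported(self.reported_raw)[2]

    def obtained_at(self, stage: Stage) -> float | str:
        """Best available obtained value at ``stage``.

        At the after-assistance stage, a value the authors' assistance did
        not touch (absent or flagged unattempted) falls back to the
        before-assistance result.
        """
        if stage is Stage.BEFORE_ASSISTANCE:
            return self.obtained_before
        if self.obtained_after is None or self.obtained_after == UNATTEMPTED:
            return self.obtained_before
        return self.obtained_after

    def final_stage(self) -> Stage:
        return (
            Stage.AFTER_ASSISTANCE
            if self.assistance_requested
            else Stage.BEFORE_ASSISTANCE
        )


@dataclass(frozen=True)
class ValueAssessment:
    article_id: str
    value_type: ValueType
    pe: float | None
    classification: Classification
    stage: Stage
    #: PE >= 10 even when a decision error takes precedence; lets tallies
    #: count p-value majors separately from the decision flag.
    major_flag: bool = False
    decision_flag: bool = False


@dataclass(frozen=True)
class ArticleAuditOutcome:
    article_id: str
    outcome: ArticleOutcome
    counts: dict[Classification, int]


@dataclass(frozen=True)
class IssueRecord:
    article_id: str
    locus: IssueLocus
    resolved_by_authors: bool


def _round_away(x: float, decimals: int) -> float:
    """Round half away from zero, the convention for printed statistics."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percentage_error(
    reported: float, obtained: float, reported_decimals: int | None = None
) -> float:
    """Percentage error of an obtained value against a reported one.

    The obtained value is first rounded to the reported value's printed
    precision (``reported_decimals``), so agreement at printed precision
    gives PE = 0.  A reported value of exactly zero has no meaningful
    relative error: PE is 0 when the obtained value also rounds to zero,
    and infinite otherwise (the caller classifies that as a major error).
    """
    if reported_decimals is not None:
        obtained = _round_away(obtained, reported_decimals)
    if reported == 0:
        return 0.0 if obtained == 0 else math.inf
    return abs(obtained - reported) / abs(reported) * 100.0


def _sides_of_boundary(p: float) -> bool:
    """True when p is on the significant side (p <= 0.05)."""
    return p <= _P_BOUNDARY


def classify_value(record: TargetValueRecord, stage: Stage) -> ValueAssessment:
    """Classify one target value at the given assistance stage.

    Order of evaluation: the insufficient-information flag wins outright;
    inequality-form reported values (almost always p-values such as
    "<0.001") match when the obtained value satisfies the inequality and
    otherwise fall to the decision rule; numeric p-values check the 0.05
    boundary (decision error takes precedence over a numeric major error);
    everything else is classified by PE alone.
    """
    obtained = record.obtained_at(stage)
    if obtained == INSUFFICIENT:
        return ValueAssessment(
            article_id=record.article_id,
            value_type=record.value_type,
            pe=None,
            classification=Classification.INSUFFICIENT_INFORMATION,
            stage=stage,
        )
    obtained = float(obtained)
    reported, decimals, ineq = _parse_reported(record.reported_raw)

    if ineq is not None:
        satisfied = obtained < reported if ineq == "<" else obtained > reported
        if satisfied:
            cls = Classification.MATCH
            decision = False
        else:
            # The printed bound fixes the reported side of 0.05.
            reported_side = _sides_of_boundary(reported) if ineq == "<" else not _sides_of_boundary(reported)
            decision = (
                record.value_type is ValueType.P_VALUE
                and _sides_of_boundary(obtained) != reported_side
            )
            cls = (
                Classification.DECISION_ERROR
                if decision
                else Classification.MAJOR_NUMERICAL
            )
        return ValueAssessment(
            article_id=record.article_id,
            value_type=record.value_type,
            pe=None,
            classification=cls,
            stage=stage,
            major_flag=cls is Classification.MAJOR_NUMERICAL,
            decision_flag=decision,
        )

    pe = percentage_error(reported, obtained, decimals)
    major = pe >= 10
    decision = record.value_type is ValueType.P_VALUE and _sides_of_boundary(
        reported
    ) != _sides_of_boundary(_round_away(obtained, decimals))
    if decision:
        cls = Classification.DECISION_ERROR
    elif math.isinf(pe) or major:
        cls = Classification.MAJOR_NUMERICAL
    elif pe > 0:
        cls = Classification.MINOR_NUMERICAL
    else:
        cls = Classification.MATCH
    return ValueAssessment(
        article_id=record.article_id,
        value_type=record.value_type,
        pe=None if math.isinf(pe) else pe,
        classification=cls,
        stage=stage,
        major_flag=major or math.isinf(pe),
        decision_flag=decision,
    )


def classify_article(records: Sequence[TargetValueRecord]) -> ArticleAuditOutcome:
    """Article-level reproducibility outcome from its target values.

    Values are evaluated at the final stage (after assistance when it was
    requested).  Any remaining blocking error (insufficient information,
    major numerical, decision) makes the article not fully reproducible.
    A clean final state is reproducible, "with assistance" when the
    before-assistance state was not already clean.
    """
    if not records:
        raise ValueError("empty record list")
    ids = {r.article_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple articles: {sorted(ids)}")
    article_id = records[0].article_id
    assistance = any(r.assistance_requested for r in records)

    final = [classify_value(r, r.final_stage()) for r in records]
    counts = {cls: 0 for cls in Classification}
    for a in final:
        counts[a.classification] += 1
    blocked = any(a.classification in BLOCKING for a in final)

    if blocked:
        outcome = (
            ArticleOutcome.NOT_FULLY_REPRODUCIBLE_DESPITE_ASSISTANCE
            if assistance
            else ArticleOutcome.NOT_FULLY_REPRODUCIBLE
        )
    else:
        before = [classify_value(r, Stage.BEFORE_ASSISTANCE) for r in records]
        needed_assistance = assistance and any(
            a.classification in BLOCKING for a in before
        )
        outcome = (
            ArticleOutcome.REPRODUCIBLE_WITH_ASSISTANCE
            if needed_assistance
            else ArticleOutcome.REPRODUCIBLE
        )
    return ArticleAuditOutcome(article_id=article_id, outcome=outcome, counts=counts)


def tally_value_errors(assessments: Iterable[ValueAssessment]) -> pd.DataFrame:
    """Cross-tabulate assessments: value type (rows) x classification (cols).

    Row/column order is fixed by the enum declaration; marginal totals
    equal the number of assessments.
    """
    index = [t.value for t in ValueType]
    columns = [c.value for c in Classification]
    table = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for a in assessments:
        table.loc[a.value_type.value, a.classification.value] += 1
    table.index.name = "value_type"
    table.columns.name = "classification"
    return table


def tally_issue_loci(issues: Iterable[IssueRecord]) -> pd.DataFrame:
    """Cross-tabulate reproducibility issues: locus x resolved, plus rates."""
    index = [l.value for l in IssueLocus]
    table = pd.DataFrame(0, index=index, columns=["resolved", "unresolved"], dtype=int)
    for issue in issues:
        col = "resolved" if issue.resolved_by_authors else "unresolved"
        table.loc[issue.locus.value, col] += 1
    table.index.name = "locus"
    totals = table.sum(axis=1)
    table["resolution_rate"] = (table["resolved"] / totals.where(totals > 0)).astype(float)
    return table


# ---------------------------------------------------------------------------
# CSV I/O

AUDIT_COLUMNS = (
    "article_id",
    "value_type",
    "reported_raw",
    "obtained_before",
    "obtained_after",
    "assistance_requested",
)

ISSUE_COLUMNS = ("article_id", "locus", "resolved_by_authors")


def _format_obtained(v: float | str | None) -> str:
    if v is None:
        return ""
    if isinstance(v, str):
        return v
    return repr(float(v))


def _parse_obtained(raw: str, allow_empty: bool) -> float | str | None:
    raw = raw.strip()
    if raw == "":
        if allow_empty:
            return None
        raise ValueError("obtained_before must not be empty")
    if raw in (INSUFFICIENT, UNATTEMPTED):
        return raw
    return float(raw)


def read_audit_table(path: str | Path) -> list[TargetValueRecord]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in AUDIT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"audit table missing column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(reader):
            try:
                records.append(
                    TargetValueRecord(
                        article_id=row["article_id"],
                        value_type=ValueType(row["value_type"]),
                        reported_raw=row["reported_raw"],
                        obtained_before=_parse_obtained(row["obtained_before"], False),
                        obtained_after=_parse_obtained(row["obtained_after"], True),
                        assistance_requested=row["assistance_requested"]
                        in ("true", "True", "1"),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"audit table row {i}: {exc}") from exc
    return records


def write_audit_table(records: Sequence[TargetValueRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(AUDIT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.article_id,
                    r.value_type.value,
                    r.reported_raw,
                    _format_obtained(r.obtained_before),
                    _format_obtained(r.obtained_after),
                    "true" if r.assistance_requested else "false",
                ]
            )


def read_issue_table(path: str | Path) -> list[IssueRecord]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ISSUE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"issue table missing column(s): {', '.join(missing)}")
        return [
            IssueRecord(
                article_id=row["article_id"],
                locus=IssueLocus(row["locus"]),
                resolved_by_authors=row["resolved_by_authors"] in ("true", "True", "1"),
            )
            for row in reader
        ]


def write_issue_table(issues: Sequence[IssueRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ISSUE_COLUMNS)
        for issue in issues:
            writer.writerow(
                [
                    issue.article_id,
                    issue.locus.value,
                    "true" if issue.resolved_by_authors else "false",
                ]
            )
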