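"""Article coding table: domain types, CSV I/O, and descriptive summaries.

The unit of analysis is a journal article coded for its data-availability
statement (DAS) and, conditional on a DAS, for whether the shared data were
accessible, complete and understandable.  An article whose data pass all
three checks is "in-principle reusable".  A journal-wide open-data policy
takes effect on a fixed calendar date; the policy applies to every article
*submitted* on or after that date, so the submission date determines the
pre-/post-policy period.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Statement",
    "AccessRoute",
    "Accessible",
    "Complete",
    "Understandable",
    "Licence",
    "ArticleRecord",
    "CodingTable",
    "CascadeSummary",
    "PeriodCascade",
    "TimeBin",
    "SchemaError",
    "RowError",
    "ValidationError",
    "read_coding_table",
    "write_coding_table",
    "derive_period_and_reusability",
    "summarize_cascade",
    "bin_time_series",
]


class SchemaError(ValueError):
    """The CSV header does not match the documented coding schema."""


class RowError(ValueError):
    """A CSV row could not be converted into a valid :class:`ArticleRecord`."""

    def __init__(self, row_index: int, message: str) -> None:
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class ValidationError(ValueError):
    """An in-memory record violates a coding-schema invariant."""


class Statement(enum.Enum):
    DATA_AVAILABLE = "data_available"
    DATA_NOT_AVAILABLE = "data_not_available"
    NO_STATEMENT = "no_statement"


class AccessRoute(enum.Enum):
    PERSONAL_WEBSITE = "personal_website"
    THIRD_PARTY_REPOSITORY = "third_party_repository"
    JOURNAL_SUPPLEMENTARY = "journal_supplementary"
    OTHER = "other"
    NONE = "none"


class Accessible(enum.Enum):
    YES = "yes"
    NO = "no"
    SOME_FILES = "some_files"
    NOT_APPLICABLE = "not_applicable"


class Complete(enum.Enum):
    ALL = "all"
    SOME = "some"
    UNCLEAR = "unclear"
    NOT_APPLICABLE = "not_applicable"


class Understandable(enum.Enum):
    YES = "yes"
    PARTLY = "partly"
    NO = "no"
    NOT_APPLICABLE = "not_applicable"


class Licence(enum.Enum):
    CC_BY = "cc_by"
    CC_0 = "cc_0"
    OTHER = "other"
    NONE = "none"


# Header of the coding-table CSV, in column order.
CODING_COLUMNS = (
    "article_id",
    "submission_date",
    "statement",
    "access_route",
    "accessible",
    "complete",
    "understandable",
    "has_scripts",
    "licence",
)

# Fields that use the empty CSV cell to mean "not applicable" / "none".
_NA_DEFAULTS = {
    "access_route": AccessRoute.NONE,
    "accessible": Accessible.NOT_APPLICABLE,
    "complete": Complete.NOT_APPLICABLE,
    "understandable": Understandable.NOT_APPLICABLE,
}


@dataclass(frozen=True)
class ArticleRecord:
    """One coded article.

    Invariants enforced at construction:

    * ``access_route`` is :attr:`AccessRoute.NONE` exactly when the article
      has no data-available statement;
    * the accessibility / completeness / understandability codes are
      ``not_applicable`` exactly when there is no data-available statement.
    """

    article_id: str
    submission_date: date
    statement: Statement
    access_route: AccessRoute = AccessRoute.NONE
    accessible: Accessible = Accessible.NOT_APPLICABLE
    complete: Complete = Complete.NOT_APPLICABLE
    understandable: Understandable = Understandable.NOT_APPLICABLE
    has_scripts: bool = False
    licence: Licence = Licence.NONE

    def __post_init__(self) -> None:
        has_das = self.statement is Statement.DATA_AVAILABLE
        if (self.access_route is not AccessRoute.NONE) != has_das:
            raise ValidationError(
                f"article {self.article_id!r}: access_route={self.access_route.value!r} "
                f"inconsistent with statement={self.statement.value!r}"
            )
        for name, na in (
            ("accessible", Accessible.NOT_APPLICABLE),
            ("complete", Complete.NOT_APPLICABLE),
            ("understandable", Understandable.NOT_APPLICABLE),
        ):
            value = getattr(self, name)
            if (value is not na) != has_das:
                raise ValidationError(
                    f"article {self.article_id!r}: {name}={value.value!r} "
                    f"inconsistent with statement={self.statement.value!r}"
                )

    @property
    def has_das(self) -> bool:
        return self.statement is Statement.DATA_AVAILABLE

    @property
    def reusable(self) -> bool:
        """In-principle reusable: accessible, complete and understandable.

        Partial codes (``some_files``, ``some``, ``unclear``, ``partly``)
        do not qualify.
        """
        return (
            self.accessible is Accessible.YES
            and self.complete is Complete.ALL
            and self.understandable is Understandable.YES
        )


@dataclass(frozen=True)
class CodingTable:
    """An ordered collection of coded articles plus the policy date."""

    records: tuple[ArticleRecord, ...]
    policy_date: date

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.article_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate article_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class PeriodCascade:
    """Reusability cascade counts for one policy period."""

    n_articles: int
    n_das: int
    n_accessible: int
    n_complete_and_understandable: int
    n_reusable: int

    def __post_init__(self) -> None:
        seq = (
            self.n_articles,
            self.n_das,
            self.n_accessible,
            self.n_complete_and_understandable,
        )
        if (
            any(a < b for a, b in zip(seq, seq[1:]))
            or self.n_reusable > self.n_complete_and_understandable
        ):
            raise ValidationError(f"cascade counts not monotone: {self}")

    def proportions(self) -> dict[str, float | None]:
        """Each stage as a fraction of the preceding non-zero stage."""

        def frac(num: int, den: int) -> float | None:
            return num / den if den else None

        return {
            "das_of_articles": frac(self.n_das, self.n_articles),
            "accessible_of_das": frac(self.n_accessible, self.n_das),
            "reusable_of_das": frac(self.n_reusable, self.n_das),
            "reusable_of_articles": frac(self.n_reusable, self.n_articles),
        }


@dataclass(frozen=True)
class CascadeSummary:
    pre: PeriodCascade
    post: PeriodCascade

    def to_json(self) -> str:
        payload = {
            period: {**dataclasses.asdict(cascade), "proportions": cascade.proportions()}
            for period, cascade in (("pre", self.pre), ("post", self.post))
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class TimeBin:
    """One half-open bin of the article time series."""

    midpoint: float  # days from policy
    n: int
    proportion: float


def _parse_enum(cls, raw: str, column: str):
    if raw == "" and column in _NA_DEFAULTS:
        return _NA_DEFAULTS[column]
    try:
        return cls(raw)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValueError(f"{column}={raw!r} not one of: {allowed}") from None


def _parse_bool(raw: str) -> bool:
    if raw in ("true", "True", "1"):
        return True
    if raw in ("false", "False", "0"):
        return False
    raise ValueError(f"has_scripts={raw!r} is not a boolean")


def read_coding_table(path: str | Path, policy_date: date) -> CodingTable:
    """Read a coding-table CSV into a validated :class:`CodingTable`.

    The file must carry the documented lower-snake-case header; dates are
    ISO-8601; the empty cell encodes ``none`` / ``not_applicable``.
    Raises :class:`SchemaError` for a malformed header and :class:`RowError`
    (carrying the 0-based data-row index) for a bad row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CODING_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(reader):
            try:
                records.append(
                    ArticleRecord(
                        article_id=row["article_id"],
                        submission_date=datetime.strptime(
                            row["submission_date"], "%Y-%m-%d"
                        ).date(),
                        statement=_parse_enum(Statement, row["statement"], "statement"),
                        access_route=_parse_enum(
                            AccessRoute, row["access_route"], "access_route"
                        ),
                        accessible=_parse_enum(Accessible, row["accessible"], "accessible"),
                        complete=_parse_enum(Complete, row["complete"], "complete"),
                        understandable=_parse_enum(
                            Understandable, row["understandable"], "understandable"
                        ),
                        has_scripts=_parse_bool(row["has_scripts"]),
                        licence=_parse_enum(Licence, row["licence"], "licence"),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise RowError(i, str(exc)) from exc
    return CodingTable(records=tuple(records), policy_date=policy_date)


def write_coding_table(table: CodingTable, path: str | Path) -> None:
    """Write ``table`` so that :func:`read_coding_table` round-trips it."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CODING_COLUMNS)
        for r in table:
            writer.writerow(
                [
                    r.article_id,
                    r.submission_date.isoformat(),
                    r.statement.value,
                    "" if r.access_route is AccessRoute.NONE else r.access_route.value,
                    "" if r.accessible is Accessible.NOT_APPLICABLE else r.accessible.value,
                    "" if r.complete is Complete.NOT_APPLICABLE else r.complete.value,
                    ""
                    if r.understandable is Understandable.NOT_APPLICABLE
                    else r.understandable.value,
                    "true" if r.has_scripts else "false",
                    r.licence.value,
                ]
            )


def derive_period_and_reusability(table: CodingTable) -> pd.DataFrame:
    """Annotate the table with period and reusability columns.

    Returns a DataFrame with one row per article (input order preserved)
    carrying ``das``, ``reusable``, ``days_from_policy`` (signed integer
    days, negative pre-policy) and ``post``.  An article submitted exactly
    on the policy date is post-policy: the policy applied to articles
    submitted on or after that date.
    """
    rows = []
    for r in table:
        days = (r.submission_date - table.policy_date).days
        rows.append(
            {
                "article_id": r.article_id,
                "submission_date": r.submission_date,
                "das": r.has_das,
                "reusable": r.reusable,
                "days_from_policy": days,
                "post": days >= 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "article_id",
            "submission_date",
            "das",
            "reusable",
            "days_from_policy",
            "post",
        ],
    )


def _cascade_for(records: Sequence[ArticleRecord]) -> PeriodCascade:
    das = [r for r in records if r.has_das]
    accessible = [r for r in das if r.accessible is Accessible.YES]
    comp_und = [
        r
        for r in accessible
        if r.complete is Complete.ALL and r.understandable is Understandable.YES
    ]
    return PeriodCascade(
        n_articles=len(records),
        n_das=len(das),
        n_accessible=len(accessible),
        n_complete_and_understandable=len(comp_und),
        n_reusable=len(comp_und),
    )


def summarize_cascade(table: CodingTable) -> CascadeSummary:
    """Count the reusability cascade separately for each policy period."""
    pre = [r for r in table if r.submission_date < table.policy_date]
    post = [r for r in table if r.submission_date >= table.policy_date]
    return CascadeSummary(pre=_cascade_for(pre), post=_cascade_for(post))


def bin_time_series(
    table: CodingTable, bin_width: int = 50, outcome: str = "das"
) -> list[TimeBin]:
    """Binned proportion series of a binary outcome over submission time.

    Bins are half-open ``[left, right)`` in days from the policy date,
    anchored so that day 0 starts the first post-policy bin.  ``outcome``
    is ``"das"`` or ``"reusable"``.  Empty table gives an empty list.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if outcome not in ("das", "reusable"):
        raise ValueError(f"unknown outcome field {outcome!r}")
    annotated = derive_period_and_reusability(table)
    if annotated.empty:
        return []
    idx = annotated["days_from_policy"].floordiv(bin_width)
    grouped = annotated.groupby(idx)[outcome]
    return [
        TimeBin(
            midpoint=(i + 0.5) * bin_width,
            n=int(g.size),
            proportion=float(g.mean()),
        )
        for i, g in grouped
    ]
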