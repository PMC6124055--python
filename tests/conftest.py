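"""Shared fixtures: deterministic coding tables with prescribed margins."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from odpeval.corpus import (
    Accessible,
    AccessRoute,
    ArticleRecord,
    CodingTable,
    Complete,
    Licence,
    Statement,
    Understandable,
)

POLICY = date(2015, 3, 1)


def _record(i: int, day: int, das: bool, reusable: bool) -> ArticleRecord:
    if not das:
        return ArticleRecord(
            article_id=f"T{i:04d}",
            submission_date=POLICY + timedelta(days=day),
            statement=Statement.NO_STATEMENT,
        )
    return ArticleRecord(
        article_id=f"T{i:04d}",
        submission_date=POLICY + timedelta(days=day),
        statement=Statement.DATA_AVAILABLE,
        access_route=AccessRoute.JOURNAL_SUPPLEMENTARY,
        accessible=Accessible.YES,
        complete=Complete.ALL if reusable else Complete.SOME,
        understandable=Understandable.YES if reusable else Understandable.PARTLY,
        has_scripts=False,
        licence=Licence.NONE,
    )


def make_margin_table(
    pre: tuple[int, int, int], post: tuple[int, int, int], policy: date = POLICY
) -> CodingTable:
    """Coding table with exact (n_articles, n_das, n_reusable) per period.

    Submission dates are spread across each period so the segmented
    logistic model remains estimable.
    """
    records = []
    i = 0
    for (n, n_das, n_reus), sign in ((pre, -1), (post, +1)):
        span = 1900 if sign < 0 else 500
        k = 0  # running DAS count, for spreading reusables
        for j in range(n):
            day = sign * (1 + (j * span) // max(n, 1))
            if sign > 0:
                day -= 1  # post period includes day 0
            # Spread DAS (and reusable-within-DAS) evenly over the period so
            # the outcome is not a step function of time.
            das = (j + 1) * n_das // n > j * n_das // n
            if das:
                reusable = (k + 1) * n_reus // max(n_das, 1) > k * n_reus // max(n_das, 1)
                k += 1
            else:
                reusable = False
            records.append(_record(i, day, das, reusable))
            i += 1
    return CodingTable(records=tuple(records), policy_date=policy)


@pytest.fixture(scope="session")
def reference_margin_table() -> CodingTable:
    """Corpus matching the evaluated journal's printed marginal counts."""
    return make_margin_table(pre=(417, 104, 23), post=(174, 136, 85))
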