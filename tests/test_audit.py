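"""Percentage-error taxonomy and article-level reproducibility outcomes."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odpeval.audit import (
    INSUFFICIENT,
    ArticleOutcome,
    Classification,
    IssueLocus,
    IssueRecord,
    Stage,
    TargetValueRecord,
    ValueType,
    classify_article,
    classify_value,
    percentage_error,
    read_audit_table,
    tally_issue_loci,
    tally_value_errors,
    write_audit_table,
)
from odpeval.simulate import AuditFixtureParams, generate_audit_fixture


def _record(
    reported: str,
    obtained,
    vtype: ValueType = ValueType.TEST_STATISTIC,
    after=None,
    assistance: bool = False,
    article: str = "A",
) -> TargetValueRecord:
    return TargetValueRecord(
        article_id=article,
        value_type=vtype,
        reported_raw=reported,
        obtained_before=obtained,
        obtained_after=after,
        assistance_requested=assistance,
    )


class TestPercentageError:
    @pytest.mark.parametrize(
        "reported, obtained, decimals, expected",
        [
            (2.0, 2.3, 1, 15.0),
            (5.00, 5.001, 2, 0.0),  # rounds back to the printed value
            (-0.50, -0.45, 2, 10.0),  # absolute-value denominator
            (2.0, 2.2, 1, 10.0),  # exactly on the major boundary
        ],
    )
    def test_examples(self, reported, obtained, decimals, expected):
        assert percentage_error(reported, obtained, decimals) == pytest.approx(expected)

    def test_zero_reported(self):
        assert percentage_error(0.0, 0.004, 2) == 0.0
        assert math.isinf(percentage_error(0.0, 0.2, 2))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        reported=st.floats(0.01, 1e6),
        obtained=st.floats(0.0, 1e6),
        k=st.floats(0.001, 1000),
    )
    def test_scale_invariance_before_rounding(self, reported, obtained, k):
        base = percentage_error(reported, obtained)
        scaled = percentage_error(k * reported, k * obtained)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_identity_gives_zero(self):
        assert percentage_error(3.14, 3.14) == 0.0


class TestClassifyValue:
    @pytest.mark.parametrize(
        "reported, obtained, vtype, expected",
        [
            ("0.04", 0.06, ValueType.P_VALUE, Classification.DECISION_ERROR),
            ("12.0", 13.5, ValueType.TEST_STATISTIC, Classification.MAJOR_NUMERICAL),
            ("4.20", 4.21, ValueType.MEAN_MEDIAN, Classification.MINOR_NUMERICAL),
            ("2.0", 2.2, ValueType.SD_SE, Classification.MAJOR_NUMERICAL),  # PE = 10
            ("5.00", 5.0, ValueType.MEAN_MEDIAN, Classification.MATCH),
            # p on the same side of 0.05: plain numerical classification
            ("0.30", 0.45, ValueType.P_VALUE, Classification.MAJOR_NUMERICAL),
            ("0.30", 0.31, ValueType.P_VALUE, Classification.MINOR_NUMERICAL),
        ],
    )
    def test_numeric_cases(self, reported, obtained, vtype, expected):
        assessment = classify_value(
            _record(reported, obtained, vtype), Stage.BEFORE_ASSISTANCE
        )
        assert assessment.classification is expected

    def test_decision_error_pe_flag_retained(self):
        """A p-value across the boundary with PE >= 10 keeps its major flag."""
        assessment = classify_value(
            _record("0.04", 0.30, ValueType.P_VALUE), Stage.BEFORE_ASSISTANCE
        )
        assert assessment.classification is Classification.DECISION_ERROR
        assert assessment.major_flag

    def test_boundary_p_equal_on_both_sides_is_not_decision(self):
        assessment = classify_value(
            _record("0.05", 0.05, ValueType.P_VALUE), Stage.BEFORE_ASSISTANCE
        )
        assert assessment.classification is Classification.MATCH

    @pytest.mark.parametrize(
        "obtained, expected",
        [
            (0.0005, Classification.MATCH),
            (0.002, Classification.MAJOR_NUMERICAL),  # fails bound, same side
            (0.20, Classification.DECISION_ERROR),  # crosses 0.05
        ],
    )
    def test_inequality_reported_p(self, obtained, expected):
        assessment = classify_value(
            _record("<0.001", obtained, ValueType.P_VALUE), Stage.BEFORE_ASSISTANCE
        )
        assert assessment.classification is expected
        assert assessment.pe is None  # inequality forms never carry numeric PE

    def test_insufficient_flag_wins(self):
        assessment = classify_value(
            _record("1.0", INSUFFICIENT), Stage.BEFORE_ASSISTANCE
        )
        assert assessment.classification is Classification.INSUFFICIENT_INFORMATION

    def test_after_stage_falls_back_when_unattempted(self):
        rec = _record("2.00", 2.5, after="unattempted", assistance=True)
        after = classify_value(rec, Stage.AFTER_ASSISTANCE)
        assert after.classification is Classification.MAJOR_NUMERICAL


class TestClassifyArticle:
    def test_all_match_is_reproducible(self):
        records = [_record("1.00", 1.0) for _ in range(3)]
        assert classify_article(records).outcome is ArticleOutcome.REPRODUCIBLE

    def test_only_minors_is_reproducible(self):
        records = [_record("1.00", 1.03), _record("2.00", 2.0)]
        assert classify_article(records).outcome is ArticleOutcome.REPRODUCIBLE

    def test_majors_resolved_by_assistance(self):
        records = [
            _record("2.00", 2.5, after=2.0, assistance=True),
            _record("3.00", 3.0, after=3.0, assistance=True),
        ]
        assert (
            classify_article(records).outcome
            is ArticleOutcome.REPRODUCIBLE_WITH_ASSISTANCE
        )

    def test_major_remaining_despite_assistance(self):
        records = [_record("2.00", 2.5, after=2.5, assistance=True)]
        assert (
            classify_article(records).outcome
            is ArticleOutcome.NOT_FULLY_REPRODUCIBLE_DESPITE_ASSISTANCE
        )

    def test_major_without_assistance(self):
        records = [_record("2.00", 2.5)]
        assert (
            classify_article(records).outcome is ArticleOutcome.NOT_FULLY_REPRODUCIBLE
        )

    def test_adding_major_never_improves_outcome(self):
        """Monotonicity of the article classification."""
        severity = {
            ArticleOutcome.REPRODUCIBLE: 0,
            ArticleOutcome.REPRODUCIBLE_WITH_ASSISTANCE: 1,
            ArticleOutcome.NOT_FULLY_REPRODUCIBLE: 2,
            ArticleOutcome.NOT_FULLY_REPRODUCIBLE_DESPITE_ASSISTANCE: 2,
        }
        bases = [
            [_record("1.00", 1.0)],
            [_record("1.00", 1.03)],
            [_record("2.00", 2.5, after=2.0, assistance=True)],
        ]
        for base in bases:
            before = severity[classify_article(base).outcome]
            extra = _record(
                "9.00",
                9.0 * 1.3,
                after=9.0 * 1.3 if base[0].assistance_requested else None,
                assistance=base[0].assistance_requested,
            )
            after = severity[classify_article(base + [extra]).outcome]
            assert after >= before

    def test_empty_and_mixed_article_rejected(self):
        with pytest.raises(ValueError):
            classify_article([])
        with pytest.raises(ValueError, match="multiple articles"):
            classify_article([_record("1.0", 1.0, article="A"), _record("1.0", 1.0, article="B")])


class TestTallies:
    def test_empty_input_all_zero(self):
        table = tally_value_errors([])
        assert int(table.to_numpy().sum()) == 0
        assert list(table.index) == [t.value for t in ValueType]

    def test_totals_conserved_on_random_fixture(self):
        records, issues, _ = generate_audit_fixture(AuditFixtureParams(seed=7))
        assessments = [classify_value(r, r.final_stage()) for r in records]
        table = tally_value_errors(assessments)
        assert int(table.to_numpy().sum()) == len(records)
        issue_table = tally_issue_loci(issues)
        assert int(issue_table[["resolved", "unresolved"]].to_numpy().sum()) == len(
            issues
        )

    def test_issue_resolution_rates(self):
        issues = [
            IssueRecord("A", IssueLocus.TYPOGRAPHICAL, True),
            IssueRecord("A", IssueLocus.TYPOGRAPHICAL, True),
            IssueRecord("B", IssueLocus.DATA_FILE_ISSUE, False),
        ]
        table = tally_issue_loci(issues)
        assert table.loc["typographical", "resolution_rate"] == 1.0
        assert table.loc["data_file_issue", "resolution_rate"] == 0.0


class TestAuditCsv:
    def test_roundtrip(self, tmp_path):
        records, _, _ = generate_audit_fixture(AuditFixtureParams(seed=2))
        path = tmp_path / "audit.csv"
        write_audit_table(records, path)
        assert read_audit_table(path) == records

    def test_obtained_after_requires_assistance(self):
        with pytest.raises(ValueError, match="assistance"):
            _record("1.0", 1.0, after=1.0, assistance=False)
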