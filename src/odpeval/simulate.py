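"""Seeded generators for synthetic article corpora and audit fixtures.

Two families of fixtures stand in for a hand-coded journal corpus:

* :func:`generate_corpus` draws a coding table whose data-available
  statement (DAS) indicator follows the segmented logistic ITS model and
  whose reusability fields follow a conditional cascade
  (accessible | DAS) -> (complete | accessible) -> (understandable |
  complete).  Defaults emulate the evaluated journal: 591 articles with
  submission dates spanning 1915 days pre-policy to 523 days post-policy,
  ITS coefficients implying a 1.04-fold 50-day secular trend, a 1.53-fold
  level change and a 1.14-fold trend acceleration on the risk-ratio
  scale, and period-specific cascade probabilities reproducing roughly
  22% (pre) and 62% (post) in-principle reusability among DAS articles.

* :func:`generate_audit_fixture` draws an audit table whose obtained
  values realize known error classes (fixed multipliers that land
  unambiguously inside each percentage-error band), returning the
  ground-truth labels so classifier recovery can be checked exactly.
  :func:`reference_margin_fixture` deterministically constructs the corpus
  with 35 articles and 1324 target values whose final-stage margins are
  64 major, 146 minor, 0 decision and 2 insufficient-information errors
  and whose article outcomes split 11 / 11 / 13.

A single root seed feeds named sub-streams so that adding a stream never
perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
from scipy.special import expit, logit

from .audit import (
    INSUFFICIENT,
    ArticleOutcome,
    Classification,
    IssueLocus,
    IssueRecord,
    TargetValueRecord,
    ValueType,
)
from .corpus import (
    Accessible,
    AccessRoute,
    ArticleRecord,
    CodingTable,
    Complete,
    Licence,
    Statement,
    Understandable,
)

__all__ = [
    "CorpusParams",
    "CascadeProbs",
    "AuditFixtureParams",
    "beta_from_risk_ratios",
    "generate_corpus",
    "generate_audit_fixture",
    "reference_margin_fixture",
    "DEFAULT_POLICY_DATE",
]

DEFAULT_POLICY_DATE = date(2015, 3, 1)

# Fixed stream indices: appending a stream must not shift existing ones.
_STREAMS = {"dates": 0, "outcome": 1, "cascade": 2, "extras": 3, "inject": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def beta_from_risk_ratios(
    baseline_p: float,
    trend_rr: float,
    level_rr: float,
    slope_ratio: float,
) -> tuple[float, float, float, float]:
    """ITS coefficients implying the given risk-ratio effects.

    ``baseline_p`` is the model probability immediately pre-policy,
    expit(b0).  The trend and level risk ratios anchor there; the
    post-period trend risk ratio is ``trend_rr * slope_ratio`` anchored at
    the immediately-post-policy probability.  Inverts the anchored
    odds-to-risk conversion exactly.
    """
    b0 = float(logit(baseline_p))
    b1 = float(logit(min(trend_rr * baseline_p, 1 - 1e-12))) - b0
    p_post = min(level_rr * baseline_p, 1 - 1e-12)
    b2 = float(logit(p_post)) - b0
    p_post_next = min(trend_rr * slope_ratio * p_post, 1 - 1e-12)
    b3 = float(logit(p_post_next)) - (b0 + b2) - b1
    return (b0, b1, b2, b3)


@dataclass(frozen=True)
class CascadeProbs:
    """Conditional reusability-cascade probabilities for one period.

    ``p_accessible``: P(accessible = yes | DAS); ``p_complete``:
    P(complete = all | accessible = yes); ``p_understandable``:
    P(understandable = yes | complete = all).
    """

    p_accessible: float
    p_complete: float
    p_understandable: float

    def __post_init__(self) -> None:
        for name in ("p_accessible", "p_complete", "p_understandable"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def p_reusable_given_das(self) -> float:
        return self.p_accessible * self.p_complete * self.p_understandable


# Defaults reproduce ~22% / ~62% reusable-given-DAS pre/post.
_DEFAULT_CASCADE_PRE = CascadeProbs(0.96, 0.40, 0.57)
_DEFAULT_CASCADE_POST = CascadeProbs(0.99, 0.72, 0.87)

# Access-route split among DAS articles: personal webpage / third-party
# repository / journal supplementary / other, matching the observed
# 2 / 27 / 208 / 3 of 240.
_ROUTE_PROBS = (2 / 240, 27 / 240, 208 / 240, 3 / 240)
_ROUTES = (
    AccessRoute.PERSONAL_WEBSITE,
    AccessRoute.THIRD_PARTY_REPOSITORY,
    AccessRoute.JOURNAL_SUPPLEMENTARY,
    AccessRoute.OTHER,
)


@dataclass(frozen=True)
class CorpusParams:
    n_articles: int = 591
    date_range: tuple[int, int] = (-1915, 523)
    beta: tuple[float, float, float, float] = beta_from_risk_ratios(
        0.35, 1.04, 1.53, 1.14
    )
    cascade_pre: CascadeProbs = _DEFAULT_CASCADE_PRE
    cascade_post: CascadeProbs = _DEFAULT_CASCADE_POST
    policy_date: date = DEFAULT_POLICY_DATE
    p_scripts_given_das: float = 0.075
    p_licence_given_das: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be positive")
        lo, hi = self.date_range
        if not lo < 0 < hi:
            raise ValueError("date_range must straddle the policy date (min < 0 < max)")


def generate_corpus(params: CorpusParams) -> tuple[CodingTable, CorpusParams]:
    """Draw a synthetic coding table under the ITS + cascade model.

    Submission dates are uniform (in whole days) over ``date_range``; the
    DAS indicator is Bernoulli with logit b0 + b1*t + b2*post + b3*t*post
    (t in 50-day units); reusability fields are drawn down the conditional
    cascade.  Identical parameters (including seed) give an identical
    table.  Returns the table and the ground-truth parameters.
    """
    lo, hi = params.date_range
    days = np.sort(_rng(params.seed, "dates").integers(lo, hi + 1, params.n_articles))
    t = days / 50.0
    post = (days >= 0).astype(float)
    eta = (
        params.beta[0]
        + params.beta[1] * t
        + params.beta[2] * post
        + params.beta[3] * t * post
    )
    das = _rng(params.seed, "outcome").random(params.n_articles) < expit(eta)

    cascade_rng = _rng(params.seed, "cascade")
    extras_rng = _rng(params.seed, "extras")
    records = []
    width = len(str(params.n_articles))
    for i in range(params.n_articles):
        day = int(days[i])
        submission = params.policy_date + timedelta(days=day)
        if not das[i]:
            records.append(
                ArticleRecord(
                    article_id=f"A{i:0{width}d}",
                    submission_date=submission,
                    statement=Statement.NO_STATEMENT,
                )
            )
            continue
        probs = params.cascade_post if day >= 0 else params.cascade_pre
        u = cascade_rng.random(3)
        accessible = Accessible.YES if u[0] < probs.p_accessible else (
            Accessible.NO if extras_rng.random() < 0.5 else Accessible.SOME_FILES
        )
        if accessible is Accessible.YES:
            complete = Complete.ALL if u[1] < probs.p_complete else (
                Complete.SOME if extras_rng.random() < 0.5 else Complete.UNCLEAR
            )
        else:
            complete = Complete.SOME
        if complete is Complete.ALL:
            understandable = (
                Understandable.YES
                if u[2] < probs.p_understandable
                else (
                    Understandable.PARTLY
                    if extras_rng.random() < 0.5
                    else Understandable.NO
                )
            )
        else:
            understandable = Understandable.PARTLY
        route = _ROUTES[int(extras_rng.choice(4, p=_ROUTE_PROBS))]
        records.append(
            ArticleRecord(
                article_id=f"A{i:0{width}d}",
                submission_date=submission,
                statement=Statement.DATA_AVAILABLE,
                access_route=route,
                accessible=accessible,
                complete=complete,
                understandable=understandable,
                has_scripts=bool(extras_rng.random() < params.p_scripts_given_das),
                licence=Licence.CC_BY
                if extras_rng.random() < params.p_licence_given_das
                else Licence.NONE,
            )
        )
    return CodingTable(records=tuple(records), policy_date=params.policy_date), params


# ---------------------------------------------------------------------------
# Audit fixtures

# Injection multipliers land each class unambiguously inside its PE band
# after rounding to 2 printed decimals: 3% -> minor, 25% -> major.
_MINOR_FACTOR = 1.03
_MAJOR_FACTOR = 1.25

# Value-type mix used for non-injected values (roughly the observed mix of
# audited statistics: means/SDs/tests/ps dominate).
_TYPE_MIX = (
    (ValueType.MEAN_MEDIAN, 0.25),
    (ValueType.SD_SE, 0.20),
    (ValueType.TEST_STATISTIC, 0.15),
    (ValueType.P_VALUE, 0.15),
    (ValueType.DEGREES_OF_FREEDOM, 0.10),
    (ValueType.EFFECT_SIZE, 0.07),
    (ValueType.COUNT_PROPORTION, 0.04),
    (ValueType.CONFIDENCE_INTERVAL, 0.02),
    (ValueType.MISC, 0.02),
)


@dataclass(frozen=True)
class AuditFixtureParams:
    n_articles: int = 35
    mean_values_per_article: float = 1324 / 35
    injection_rates: dict = field(
        default_factory=lambda: {
            Classification.MINOR_NUMERICAL: 146 / 1324,
            Classification.MAJOR_NUMERICAL: 64 / 1324,
            Classification.DECISION_ERROR: 0.0,
            Classification.INSUFFICIENT_INFORMATION: 2 / 1324,
        }
    )
    assistance_resolution_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.injection_rates.values())
        if total > 1:
            raise ValueError(f"injection rates sum to {total} > 1")
        for cls, rate in self.injection_rates.items():
            if rate < 0:
                raise ValueError(f"negative injection rate for {cls}")


def _reported_for(vtype: ValueType, rng: np.random.Generator) -> str:
    """A plausible printed value for a statistic of the given type."""
    if vtype is ValueType.P_VALUE:
        # Keep away from 0.05 so multiplicative injections never cross it.
        p = rng.uniform(0.20, 0.70)
        return f"{p:.2f}"
    if vtype is ValueType.DEGREES_OF_FREEDOM:
        # Integer-printed; >= 34 so a 3% perturbation still shifts the
        # rounded integer and lands in the minor band.
        return str(int(rng.integers(34, 200)))
    value = rng.uniform(1.0, 80.0)
    return f"{value:.2f}"


def _obtained_for(
    reported_raw: str, label: Classification, vtype: ValueType
) -> float | str:
    reported = float(reported_raw)
    if label is Classification.INSUFFICIENT_INFORMATION:
        return INSUFFICIENT
    if label is Classification.MATCH:
        return reported
    if label is Classification.MINOR_NUMERICAL:
        return reported * _MINOR_FACTOR
    if label is Classification.MAJOR_NUMERICAL:
        return reported * _MAJOR_FACTOR
    if label is Classification.DECISION_ERROR:
        # Move a p-value across the 0.05 boundary.
        return 0.20 if reported <= 0.05 else 0.01
    raise ValueError(label)


def generate_audit_fixture(
    params: AuditFixtureParams,
) -> tuple[list[TargetValueRecord], list[IssueRecord], dict]:
    """Random audit fixture with ground-truth error labels.

    Each value receives a true final-stage classification drawn from the
    injection rates (remainder: match); the obtained values are
    constructed to realize the label exactly.  An injected error is
    present before assistance; with probability
    ``assistance_resolution_rate`` an additional before-only error is
    planted and resolved by assistance, so both stages carry ground truth.
    Returns (audit records, issue records, ground-truth dict with
    per-value labels at both stages and per-article outcomes).
    """
    rng = _rng(params.seed, "inject")
    labels = list(params.injection_rates)
    probs = np.array([params.injection_rates[l] for l in labels])
    labels.append(Classification.MATCH)
    probs = np.append(probs, 1 - probs.sum())
    type_vals = [t for t, _ in _TYPE_MIX]
    type_probs = np.array([p for _, p in _TYPE_MIX])

    records: list[TargetValueRecord] = []
    issues: list[IssueRecord] = []
    truth_values: list[dict] = []
    truth_articles: dict[str, str] = {}
    width = len(str(params.n_articles))
    for a in range(params.n_articles):
        article_id = f"R{a:0{width}d}"
        n_values = max(1, int(rng.poisson(params.mean_values_per_article)))
        final_labels = [labels[int(k)] for k in rng.choice(len(labels), n_values, p=probs)]
        # Decide whether assistance was requested: any planted final error,
        # or a transient before-only error that assistance resolves.
        transient = [
            l is Classification.MATCH
            and rng.random() < params.assistance_resolution_rate * 0.1
            for l in final_labels
        ]
        blocking = {
            Classification.MAJOR_NUMERICAL,
            Classification.DECISION_ERROR,
            Classification.INSUFFICIENT_INFORMATION,
        }
        assistance = any(l in blocking for l in final_labels) or any(transient)
        for v, final_label in enumerate(final_labels):
            if final_label is Classification.DECISION_ERROR:
                vtype = ValueType.P_VALUE
                reported_raw = f"{rng.uniform(0.06, 0.30):.2f}"
            else:
                vtype = type_vals[int(rng.choice(len(type_vals), p=type_probs))]
                reported_raw = _reported_for(vtype, rng)
            if transient[v]:
                before_label = Classification.MAJOR_NUMERICAL
            else:
                before_label = final_label
            obtained_before = _obtained_for(reported_raw, before_label, vtype)
            obtained_after = (
                _obtained_for(reported_raw, final_label, vtype) if assistance else None
            )
            records.append(
                TargetValueRecord(
                    article_id=article_id,
                    value_type=vtype,
                    reported_raw=reported_raw,
                    obtained_before=obtained_before,
                    obtained_after=obtained_after,
                    assistance_requested=assistance,
                )
            )
            truth_values.append(
                {
                    "article_id": article_id,
                    "before": before_label.value,
                    "final": final_label.value,
                }
            )
        if any(l in blocking for l in final_labels):
            outcome = ArticleOutcome.NOT_FULLY_REPRODUCIBLE_DESPITE_ASSISTANCE
        elif assistance and any(transient):
            outcome = ArticleOutcome.REPRODUCIBLE_WITH_ASSISTANCE
        else:
            outcome = ArticleOutcome.REPRODUCIBLE
        truth_articles[article_id] = outcome.value
        n_issues = sum(1 for l in final_labels if l in blocking) // 3 + int(
            any(transient)
        )
        for _ in range(n_issues):
            issues.append(
                IssueRecord(
                    article_id=article_id,
                    locus=IssueLocus(
                        rng.choice([l.value for l in IssueLocus])
                    ),
                    resolved_by_authors=bool(rng.random() < 0.5),
                )
            )
    truth = {"values": truth_values, "articles": truth_articles}
    return records, issues, truth


# Major-error type histogram observed at the value level: 17 SD/SE, 17 p,
# 10 test statistics, 8 effect sizes, 4 means, 4 dfs, 1 count, 1 CI, 2 misc.
_MAJOR_TYPE_HISTOGRAM = (
    (ValueType.SD_SE, 17),
    (ValueType.P_VALUE, 17),
    (ValueType.TEST_STATISTIC, 10),
    (ValueType.EFFECT_SIZE, 8),
    (ValueType.MEAN_MEDIAN, 4),
    (ValueType.DEGREES_OF_FREEDOM, 4),
    (ValueType.COUNT_PROPORTION, 1),
    (ValueType.CONFIDENCE_INTERVAL, 1),
    (ValueType.MISC, 2),
)

# Issue loci: 30 underspecified analyses, 10 data-file, 5 typographical,
# 3 original-analysis, 9 unidentified; 33 resolved (24 + 8 + 1).
_ISSUE_PLAN = (
    (IssueLocus.ANALYSIS_UNDERSPECIFIED, 30, 24),
    (IssueLocus.DATA_FILE_ISSUE, 10, 8),
    (IssueLocus.TYPOGRAPHICAL, 5, 0),
    (IssueLocus.ORIGINAL_ANALYSIS_ISSUE, 3, 1),
    (IssueLocus.UNIDENTIFIED, 9, 0),
)


def reference_margin_fixture(
    seed: int = 0,
) -> tuple[list[TargetValueRecord], list[IssueRecord], dict]:
    """Deterministic fixture hitting the reference study's exact margins.

    35 articles, 1324 target values; final-stage value errors 64 major /
    146 minor / 2 insufficient / 0 decision; article outcomes 11
    reproducible, 11 reproducible with assistance, 13 not fully
    reproducible despite assistance; 57 issues across five loci with 33
    resolved.  The seed only varies the cosmetic reported values, never
    the margins.
    """
    rng = _rng(seed, "inject")
    n_articles = 35
    values_per_article = [38] * 34 + [32]  # sums to 1324
    groups = (
        [ArticleOutcome.REPRODUCIBLE] * 11
        + [ArticleOutcome.REPRODUCIBLE_WITH_ASSISTANCE] * 11
        + [ArticleOutcome.NOT_FULLY_REPRODUCIBLE_DESPITE_ASSISTANCE] * 13
    )

    # Final-stage majors (with their type histogram) and the 2 insufficient
    # values live only in the 13 not-fully-reproducible articles.
    major_types: list[ValueType] = []
    for vtype, count in _MAJOR_TYPE_HISTOGRAM:
        major_types.extend([vtype] * count)
    not_fully = [i for i, g in enumerate(groups) if
                 g is ArticleOutcome.NOT_FULLY_REPRODUCIBLE_DESPITE_ASSISTANCE]
    major_assignment: dict[int, list[ValueType]] = {i: [] for i in range(n_articles)}
    for k, vtype in enumerate(major_types):
        major_assignment[not_fully[k % len(not_fully)]].append(vtype)
    insufficient_articles = not_fully[:2]

    # 146 minors spread round-robin over all articles.
    minor_counts = [0] * n_articles
    for k in range(146):
        minor_counts[k % n_articles] += 1

    type_cycle = [t for t, _ in _TYPE_MIX]
    records: list[TargetValueRecord] = []
    issues: list[IssueRecord] = []
    truth_values: list[dict] = []
    truth_articles: dict[str, str] = {}
    for a in range(n_articles):
        article_id = f"R{a:02d}"
        outcome = groups[a]
        assistance = outcome is not ArticleOutcome.REPRODUCIBLE
        n_values = values_per_article[a]
        plan: list[tuple[Classification, Classification, ValueType]] = []
        for vtype in major_assignment[a]:
            plan.append((Classification.MAJOR_NUMERICAL, Classification.MAJOR_NUMERICAL, vtype))
        if a in insufficient_articles:
            plan.append(
                (
                    Classification.INSUFFICIENT_INFORMATION,
                    Classification.INSUFFICIENT_INFORMATION,
                    ValueType.MISC,
                )
            )
        for k in range(minor_counts[a]):
            vtype = type_cycle[k % len(type_cycle)]
            if vtype is ValueType.P_VALUE:
                vtype = ValueType.MEAN_MEDIAN  # keep p-values out of the minor band
            plan.append((Classification.MINOR_NUMERICAL, Classification.MINOR_NUMERICAL, vtype))
        if outcome is ArticleOutcome.REPRODUCIBLE_WITH_ASSISTANCE:
            # Two majors before assistance, fully resolved afterwards.
            for vtype in (ValueType.SD_SE, ValueType.TEST_STATISTIC):
                plan.append((Classification.MAJOR_NUMERICAL, Classification.MATCH, vtype))
        while len(plan) < n_values:
            vtype = type_cycle[len(plan) % len(type_cycle)]
            plan.append((Classification.MATCH, Classification.MATCH, vtype))
        if len(plan) > n_values:
            raise AssertionError("fixture plan exceeds the article's value budget")

        for before_label, final_label, vtype in plan:
            reported_raw = _reported_for(vtype, rng)
            records.append(
                TargetValueRecord(
                    article_id=article_id,
                    value_type=vtype,
                    reported_raw=reported_raw,
                    obtained_before=_obtained_for(reported_raw, before_label, vtype),
                    obtained_after=(
                        _obtained_for(reported_raw, final_label, vtype)
                        if assistance
                        else None
                    ),
                    assistance_requested=assistance,
                )
            )
            truth_values.append(
                {
                    "article_id": article_id,
                    "before": before_label.value,
                    "final": final_label.value,
                }
            )
        truth_articles[article_id] = outcome.value

    # Issues attach to the 24 assisted articles (indices 11..34) round-robin.
    assisted = list(range(11, 35))
    k = 0
    for locus, total, resolved in _ISSUE_PLAN:
        for j in range(total):
            issues.append(
                IssueRecord(
                    article_id=f"R{assisted[k % len(assisted)]:02d}",
                    locus=locus,
                    resolved_by_authors=j < resolved,
                )
            )
            k += 1

    truth = {"values": truth_values, "articles": truth_articles}
    return records, issues, truth
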