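"""Segmented logistic ITS: design, fitting, conversions, decomposition."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy.special import expit

from odpeval.its import (
    EffectLabel,
    ITSDesignRow,
    ITSFit,
    SeparationError,
    build_design,
    decompose_trend,
    estimate_effects,
    fit_its_logistic,
    predict_probability,
    vanderweele_sqrt_rr,
    zhang_yu_rr,
    _shares_and_jacobian,
)

from conftest import make_margin_table

# A fixed 12-row dataset with both outcome classes in both periods.
TWELVE_ROWS = [
    ITSDesignRow(0, -3.0, 0),
    ITSDesignRow(1, -3.0, 0),
    ITSDesignRow(0, -2.0, 0),
    ITSDesignRow(0, -2.0, 0),
    ITSDesignRow(1, -1.0, 0),
    ITSDesignRow(0, -1.0, 0),
    ITSDesignRow(1, 0.0, 1),
    ITSDesignRow(0, 0.0, 1),
    ITSDesignRow(1, 1.0, 1),
    ITSDesignRow(1, 1.0, 1),
    ITSDesignRow(0, 2.0, 1),
    ITSDesignRow(1, 2.0, 1),
]


def brute_force_mle(rows) -> np.ndarray:
    """Independent likelihood maximization via scipy's BFGS on the NLL."""
    y = np.array([r.outcome for r in rows], dtype=float)
    X = np.array([[1.0, r.time, r.post, r.time * r.post] for r in rows])

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0, eta) - y * eta))

    def grad(beta):
        return X.T @ (expit(X @ beta) - y)

    res = optimize.minimize(nll, np.zeros(4), jac=grad, method="BFGS", tol=1e-14)
    return res.x


class TestDesign:
    @pytest.mark.parametrize(
        "day, time, post",
        [(-100, -2.0, 0), (0, 0.0, 1), (523, 10.46, 1)],
    )
    def test_time_units_and_boundary(self, day, time, post):
        table = make_margin_table(pre=(4, 2, 1), post=(4, 2, 1))
        # Splice in a record at the requested day via a fresh single-row table.
        from datetime import timedelta

        from odpeval.corpus import ArticleRecord, CodingTable, Statement

        rec = ArticleRecord(
            "probe", table.policy_date + timedelta(days=day), Statement.NO_STATEMENT
        )
        single = CodingTable(records=(rec,), policy_date=table.policy_date)
        row = build_design(single)[0]
        assert row.time == pytest.approx(time)
        assert row.post == post
        assert row.interaction == pytest.approx(time * post)

    def test_unknown_outcome_rejected(self):
        table = make_margin_table(pre=(4, 2, 1), post=(4, 2, 1))
        with pytest.raises(ValueError, match="outcome"):
            build_design(table, outcome="citations")

    def test_pre_row_with_nonnegative_time_rejected(self):
        with pytest.raises(ValueError):
            ITSDesignRow(1, 0.0, 0)


class TestFit:
    def test_small_instance_matches_brute_force(self):
        fit = fit_its_logistic(TWELVE_ROWS)
        oracle = brute_force_mle(TWELVE_ROWS)
        assert np.allclose(fit.beta, oracle, atol=1e-6)

    def test_vcov_is_inverse_observed_information(self):
        fit = fit_its_logistic(TWELVE_ROWS)
        X = np.array([[1.0, r.time, r.post, r.time * r.post] for r in TWELVE_ROWS])
        p = expit(X @ np.array(fit.beta))
        info = X.T @ (X * (p * (1 - p))[:, None])
        assert np.allclose(fit.vcov_matrix, np.linalg.inv(info), rtol=1e-5)

    def test_separation_raises(self):
        rows = [r for r in TWELVE_ROWS if r.post == 0] + [
            ITSDesignRow(1, 0.0, 1),
            ITSDesignRow(1, 1.0, 1),
        ]
        with pytest.raises(SeparationError):
            fit_its_logistic(rows)

    def test_null_model_recovery(self):
        """Under beta = 0 the Wald CIs cover zero at roughly nominal rate."""
        rng = np.random.default_rng(20240301)
        n, reps, z = 5000, 100, 1.959963984540054
        covered = np.zeros(4)
        for _ in range(reps):
            t = rng.uniform(-38.3, 10.46, n)
            post = (t >= 0).astype(int)
            t = np.where(post == 0, np.minimum(t, -1e-9), t)
            y = (rng.random(n) < 0.5).astype(int)
            rows = [
                ITSDesignRow(int(yi), float(ti), int(pi))
                for yi, ti, pi in zip(y, t, post)
            ]
            fit = fit_its_logistic(rows)
            se = np.sqrt(np.diag(fit.vcov_matrix))
            covered += np.abs(np.array(fit.beta)) <= z * se
        assert (covered / reps >= 0.90).all()


class TestConversions:
    @pytest.mark.parametrize(
        "odds_ratio, p0, expected",
        [(1.0, 0.3, 1.0), (2.0, 0.5, 4 / 3), (2.0, 1e-12, 2.0)],
    )
    def test_zhang_yu_values(self, odds_ratio, p0, expected):
        assert zhang_yu_rr(odds_ratio, p0) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(b0=st.floats(-4, 4), b2=st.floats(-4, 4))
    def test_zhang_yu_equals_expit_ratio(self, b0, b2):
        """Exact identity with the logistic-model probability ratio."""
        rr = zhang_yu_rr(math.exp(b2), expit(b0))
        assert rr == pytest.approx(expit(b0 + b2) / expit(b0), abs=1e-12, rel=1e-12)

    def test_zhang_yu_domain(self):
        with pytest.raises(ValueError):
            zhang_yu_rr(2.0, 1.0)
        with pytest.raises(ValueError):
            zhang_yu_rr(-1.0, 0.5)

    @pytest.mark.parametrize("odds_ratio, expected", [(1, 1), (4, 2), (2.25, 1.5)])
    def test_sqrt_transformation(self, odds_ratio, expected):
        assert vanderweele_sqrt_rr(odds_ratio) == pytest.approx(expected)


def _fit_with(beta, vcov=None) -> ITSFit:
    vcov = np.eye(4) * 0.01 if vcov is None else np.asarray(vcov)
    return ITSFit(
        beta=tuple(beta),
        vcov=tuple(tuple(row) for row in vcov),
        log_likelihood=0.0,
        n=100,
        converged=True,
    )


class TestEffects:
    def test_level_change_closed_form(self):
        effects = {e.label: e for e in estimate_effects(_fit_with([0, 0, math.log(2), 0]))}
        level = effects[EffectLabel.LEVEL_CHANGE]
        assert level.odds_ratio == pytest.approx(2.0)
        assert level.anchor_probability == pytest.approx(0.5)
        assert level.risk_ratio == pytest.approx(4 / 3)
        assert level.ci[0] < level.risk_ratio < level.ci[1]

    def test_rare_outcome_ci_degenerates_to_wald(self):
        """With a near-zero anchor the RR CI collapses onto the OR Wald CI."""
        vcov = np.diag([1e-12, 1e-12, 0.04, 1e-12])
        fit = _fit_with([-20.0, 0.0, 0.7, 0.0], vcov)
        level = {e.label: e for e in estimate_effects(fit)}[EffectLabel.LEVEL_CHANGE]
        z = 1.959963984540054
        assert level.ci[0] == pytest.approx(math.exp(0.7 - z * 0.2), rel=1e-6)
        assert level.ci[1] == pytest.approx(math.exp(0.7 + z * 0.2), rel=1e-6)

    def test_slope_ratio_is_trend_rr_ratio(self):
        fit = fit_its_logistic(TWELVE_ROWS)
        effects = {e.label: e for e in estimate_effects(fit)}
        assert effects[EffectLabel.SLOPE_RATIO].risk_ratio == pytest.approx(
            effects[EffectLabel.POST_TREND].risk_ratio
            / effects[EffectLabel.PRE_TREND].risk_ratio
        )

    def test_risk_ratio_between_one_and_odds_ratio(self):
        for effect in estimate_effects(fit_its_logistic(TWELVE_ROWS)):
            if effect.label is EffectLabel.SLOPE_RATIO:
                continue
            lo, hi = sorted((1.0, effect.odds_ratio))
            assert lo - 1e-12 <= effect.risk_ratio <= hi + 1e-12


class TestDecomposition:
    def test_additive_case_shares(self):
        b1 = 2 * math.log(1.1)
        b2 = 2 * math.log(1.4)
        b3 = 2 * math.log(1.5) - b1 - b2
        decomp = decompose_trend(_fit_with([0.0, b1, b2, b3]))
        assert decomp.rr_time == pytest.approx(1.1)
        assert decomp.rr_policy == pytest.approx(1.4)
        assert decomp.rr_joint == pytest.approx(1.5)
        assert decomp.share_baseline == pytest.approx(0.2)
        assert decomp.share_policy == pytest.approx(0.8)
        assert decomp.share_interaction == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        b1=st.floats(-0.5, 1.0),
        b2=st.floats(-0.5, 2.0),
        b3=st.floats(-0.5, 1.0),
    )
    def test_shares_sum_to_one(self, b1, b2, b3):
        if b1 + b2 + b3 <= 0.05:  # rr_joint must exceed 1
            return
        decomp = decompose_trend(_fit_with([0.0, b1, b2, b3]))
        total = decomp.share_baseline + decomp.share_policy + decomp.share_interaction
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_delta_se_matches_numerical_gradient(self):
        beta123 = np.array([0.1, 0.6, 0.2])
        _, jac = _shares_and_jacobian(beta123)
        eps = 1e-6
        num = np.empty((3, 3))
        for j in range(3):
            up, dn = beta123.copy(), beta123.copy()
            up[j] += eps
            dn[j] -= eps
            num[:, j] = (_shares_and_jacobian(up)[0] - _shares_and_jacobian(dn)[0]) / (
                2 * eps
            )
        assert np.allclose(jac, num, atol=1e-6)

    def test_undefined_when_joint_rr_at_most_one(self):
        with pytest.raises(ValueError, match="undefined"):
            decompose_trend(_fit_with([0.0, -0.2, 0.1, 0.0]))

    def test_one_sided_pvalues_in_unit_interval(self):
        decomp = decompose_trend(_fit_with([0.0, 0.1, 0.7, 0.2]))
        assert all(0 <= p <= 1 for p in decomp.p_one_sided)
        assert all(lo <= mid <= hi for (lo, hi), mid in zip(
            decomp.ci,
            (decomp.share_baseline, decomp.share_policy, decomp.share_interaction),
        ))


class TestPredict:
    def test_null_fit_gives_half_everywhere(self):
        fit = _fit_with([0.0, 0.0, 0.0, 0.0])
        for time, post in ((-5.0, 0), (3.0, 1)):
            p, (lo, hi) = predict_probability(fit, time, post)
            assert p == pytest.approx(0.5)
            assert 0 <= lo <= p <= hi <= 1

    def test_monotone_in_time_without_interaction(self):
        fit = _fit_with([0.0, 0.3, 0.2, 0.0])
        probs = [predict_probability(fit, t, 1)[0] for t in (0.0, 1.0, 2.0, 5.0)]
        assert probs == sorted(probs)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        b=st.tuples(*[st.floats(-2, 2)] * 4),
        time=st.floats(-30, 10),
        post=st.booleans(),
    )
    def test_matches_direct_expit(self, b, time, post):
        if not post and time >= 0:
            time = -abs(time) - 0.1
        fit = _fit_with(b)
        p, _ = predict_probability(fit, time, int(post))
        eta = b[0] + b[1] * time + b[2] * post + b[3] * time * post
        assert p == pytest.approx(float(expit(eta)), abs=1e-12)
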