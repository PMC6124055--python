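"""Segmented logistic interrupted time-series (ITS) model.

The outcome trajectory of a binary article-level variable is modelled as

    logit P(y = 1) = b0 + b1*time + b2*post + b3*time*post

with ``time`` in 50-day units since the policy date (negative pre-policy)
and ``post`` the policy-period indicator.  exp(b2) is the odds ratio for
the level change at the policy date, exp(b1) the pre-policy secular trend
per 50 days, and exp(b3) the multiplicative change in that trend
post-policy.

Effects are reported on the risk-ratio scale.  The exact odds-to-risk
conversion anchored at baseline risk P0 is

    RR = OR / ((1 - P0) + P0 * OR),

which coincides with the ratio of model probabilities when OR and P0 come
from the same logistic fit.  The trend decomposition instead uses the
square-root approximation RR ~= sqrt(OR), appropriate for common outcomes,
so that the joint 50-day post-period effect splits additively (on the
excess-relative-risk scale) into baseline-trend, policy and interaction
components.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .corpus import CodingTable, derive_period_and_reusability

__all__ = [
    "DAYS_PER_UNIT",
    "ITSDesignRow",
    "ITSFit",
    "EffectEstimate",
    "TrendDecomposition",
    "EffectLabel",
    "SeparationError",
    "ConvergenceError",
    "build_design",
    "fit_its_logistic",
    "fit_its",
    "zhang_yu_rr",
    "vanderweele_sqrt_rr",
    "estimate_effects",
    "decompose_trend",
    "predict_probability",
]

DAYS_PER_UNIT = 50.0


class SeparationError(RuntimeError):
    """The outcome is perfectly (or quasi-) separated; the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """The IRLS/Newton iterations failed to converge."""


class EffectLabel(enum.Enum):
    LEVEL_CHANGE = "level_change"
    PRE_TREND = "pre_trend"
    POST_TREND = "post_trend"
    SLOPE_RATIO = "slope_ratio"


@dataclass(frozen=True)
class ITSDesignRow:
    outcome: int
    time: float
    post: int

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1) or self.post not in (0, 1):
            raise ValueError("outcome and post must be 0/1")
        if self.post == 0 and self.time >= 0:
            raise ValueError("pre-policy rows must have time < 0")

    @property
    def interaction(self) -> float:
        return self.time * self.post


@dataclass(frozen=True)
class ITSFit:
    beta: tuple[float, float, float, float]
    vcov: tuple[tuple[float, ...], ...]
    log_likelihood: float
    n: int
    converged: bool

    @property
    def vcov_matrix(self) -> np.ndarray:
        return np.asarray(self.vcov, dtype=float)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


@dataclass(frozen=True)
class EffectEstimate:
    label: EffectLabel
    odds_ratio: float
    anchor_probability: float
    risk_ratio: float
    ci: tuple[float, float]
    p_value: float
    sided: str = "two"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["label"] = self.label.value
        return d


@dataclass(frozen=True)
class TrendDecomposition:
    """Additive attribution of the joint 50-day post-period risk ratio.

    ``rr_joint`` is the risk ratio for joint exposure to one 50-day
    interval and the policy; the excess ``rr_joint - 1`` splits into a
    baseline-trend share, a policy share, and an interaction share (the
    relative excess risk due to interaction, divided by the joint excess).
    The three shares sum to one identically.
    """

    rr_time: float
    rr_policy: float
    rr_joint: float
    share_baseline: float
    share_policy: float
    share_interaction: float
    se: tuple[float, float, float]
    ci: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    p_one_sided: tuple[float, float, float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_design(table: CodingTable, outcome: str = "das") -> list[ITSDesignRow]:
    """Turn a coding table into ITS design rows.

    ``outcome`` is ``"das"`` or ``"reusable"``.  ``time`` is days from the
    policy date divided by 50; an article submitted exactly on the policy
    date has time 0 and post 1.
    """
    annotated = derive_period_and_reusability(table)
    if outcome not in ("das", "reusable"):
        raise ValueError(f"unknown outcome field {outcome!r}")
    return [
        ITSDesignRow(
            outcome=int(getattr(row, outcome)),
            time=row.days_from_policy / DAYS_PER_UNIT,
            post=int(row.post),
        )
        for row in annotated.itertuples()
    ]


def _design_matrix(rows: Sequence[ITSDesignRow]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([r.outcome for r in rows], dtype=float)
    t = np.array([r.time for r in rows], dtype=float)
    post = np.array([r.post for r in rows], dtype=float)
    X = np.column_stack([np.ones_like(t), t, post, t * post])
    return X, y


def fit_its_logistic(
    rows: Sequence[ITSDesignRow], tol: float = 1e-8, maxiter: int = 100
) -> ITSFit:
    """Maximum-likelihood fit of the segmented logistic model.

    Fitted by iteratively reweighted least squares; the covariance matrix
    is the inverse observed information at the optimum.  Raises
    :class:`SeparationError` when either period lacks both outcome classes
    (a sure sign the MLE does not exist) and :class:`ConvergenceError`
    when the iterations do not converge.
    """
    if len(rows) < 4:
        raise ValueError("need at least 4 observations to fit 4 coefficients")
    X, y = _design_matrix(rows)
    post = X[:, 2]
    for period, mask in (("pre", post == 0), ("post", post == 1)):
        if not mask.any() or len(np.unique(y[mask])) < 2:
            raise SeparationError(
                f"{period}-policy period lacks both outcome classes; "
                "the segmented-model MLE does not exist"
            )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(tol=tol, maxiter=maxiter)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise SeparationError(str(exc)) from exc
    if not res.converged:
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(deviance trace: {getattr(res, 'fit_history', {}).get('deviance', [])})"
        )
    beta = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 30:
        raise SeparationError("diverging coefficients indicate separation")
    vcov = np.asarray(res.cov_params(), dtype=float)
    return ITSFit(
        beta=tuple(float(b) for b in beta),
        vcov=tuple(tuple(float(v) for v in row) for row in vcov),
        log_likelihood=float(res.llf),
        n=len(rows),
        converged=bool(res.converged),
    )


def fit_its(table: CodingTable, outcome: str = "das") -> ITSFit:
    """Convenience wrapper: coding table -> design -> fitted model."""
    return fit_its_logistic(build_design(table, outcome=outcome))


def zhang_yu_rr(odds_ratio: float, p0: float) -> float:
    """Convert an odds ratio to a risk ratio at baseline risk ``p0``.

    RR = OR / ((1 - P0) + P0 * OR).  Exact when OR and P0 come from the
    same logistic model: then RR equals the ratio of outcome probabilities.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if not 0 <= p0 < 1:
        raise ValueError("p0 must be in [0, 1)")
    return odds_ratio / ((1 - p0) + p0 * odds_ratio)


def vanderweele_sqrt_rr(odds_ratio: float) -> float:
    """Square-root OR-to-RR approximation for common outcomes."""
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    return math.sqrt(odds_ratio)


# Contrast vectors on the coefficient scale for each effect's odds ratio,
# and the (numerator, anchor) linear predictors used for the conversion.
_EFFECT_SPECS: dict[EffectLabel, dict] = {
    EffectLabel.LEVEL_CHANGE: {
        "or_contrast": np.array([0.0, 0.0, 1.0, 0.0]),
        "anchor": np.array([1.0, 0.0, 0.0, 0.0]),
    },
    EffectLabel.PRE_TREND: {
        "or_contrast": np.array([0.0, 1.0, 0.0, 0.0]),
        "anchor": np.array([1.0, 0.0, 0.0, 0.0]),
    },
    EffectLabel.POST_TREND: {
        "or_contrast": np.array([0.0, 1.0, 0.0, 1.0]),
        "anchor": np.array([1.0, 0.0, 1.0, 0.0]),
    },
}


def _log_rr_and_grad(
    beta: np.ndarray, anchor: np.ndarray, or_contrast: np.ndarray
) -> tuple[float, np.ndarray]:
    """log RR = log expit(anchor + contrast) - log expit(anchor), with gradient.

    d/db log expit(eta) = (1 - expit(eta)) * d eta / d b.
    """
    eta0 = float(anchor @ beta)
    eta1 = float((anchor + or_contrast) @ beta)
    p0, p1 = expit(eta0), expit(eta1)
    log_rr = math.log(p1) - math.log(p0)
    grad = (1 - p1) * (anchor + or_contrast) - (1 - p0) * anchor
    return log_rr, grad


def estimate_effects(fit: ITSFit, level: float = 0.95) -> list[EffectEstimate]:
    """Level-change, trend and slope-ratio effects on the risk-ratio scale.

    Each odds ratio is converted with the anchored odds-to-risk formula:
    the level change and pre-trend anchor at the model probability
    immediately pre-policy, expit(b0); the post-trend anchors at
    expit(b0 + b2); the slope ratio is the ratio of the converted trend
    risk ratios.  CIs are delta-method intervals on the log-RR scale;
    p-values are two-sided Wald tests of the corresponding coefficient
    contrast (b2, b1, b1 + b3, and b3 for the slope ratio).
    """
    if not fit.converged:
        raise ConvergenceError("cannot derive effects from a non-converged fit")
    beta = np.asarray(fit.beta)
    vcov = fit.vcov_matrix
    z = stats.norm.ppf(1 - (1 - level) / 2)

    results: list[EffectEstimate] = []
    log_rrs: dict[EffectLabel, tuple[float, np.ndarray]] = {}
    for label, spec in _EFFECT_SPECS.items():
        contrast, anchor = spec["or_contrast"], spec["anchor"]
        log_or = float(contrast @ beta)
        log_rr, grad = _log_rr_and_grad(beta, anchor, contrast)
        log_rrs[label] = (log_rr, grad)
        se_log_rr = math.sqrt(float(grad @ vcov @ grad))
        se_contrast = math.sqrt(float(contrast @ vcov @ contrast))
        wald = log_or / se_contrast
        results.append(
            EffectEstimate(
                label=label,
                odds_ratio=math.exp(log_or),
                anchor_probability=float(expit(anchor @ beta)),
                risk_ratio=math.exp(log_rr),
                ci=(
                    math.exp(log_rr - z * se_log_rr),
                    math.exp(log_rr + z * se_log_rr),
                ),
                p_value=float(2 * stats.norm.sf(abs(wald))),
            )
        )

    # Slope ratio: post-trend RR / pre-trend RR; Wald p on b3.
    lr_post, g_post = log_rrs[EffectLabel.POST_TREND]
    lr_pre, g_pre = log_rrs[EffectLabel.PRE_TREND]
    log_sr = lr_post - lr_pre
    grad = g_post - g_pre
    se_sr = math.sqrt(float(grad @ vcov @ grad))
    b3_contrast = np.array([0.0, 0.0, 0.0, 1.0])
    wald = float(b3_contrast @ beta) / math.sqrt(float(b3_contrast @ vcov @ b3_contrast))
    results.append(
        EffectEstimate(
            label=EffectLabel.SLOPE_RATIO,
            odds_ratio=math.exp(float(beta[3])),
            anchor_probability=float(expit(beta[0] + beta[2])),
            risk_ratio=math.exp(log_sr),
            ci=(math.exp(log_sr - z * se_sr), math.exp(log_sr + z * se_sr)),
            p_value=float(2 * stats.norm.sf(abs(wald))),
        )
    )
    return results


def _shares_and_jacobian(beta123: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decomposition shares and their Jacobian w.r.t. (b1, b2, b3).

    With a = exp(b1/2), b = exp(b2/2), j = exp((b1+b2+b3)/2) (sqrt-OR risk
    ratios), the shares of the joint excess j - 1 are

        s1 = (a - 1)/(j - 1),  s2 = (b - 1)/(j - 1),
        s3 = (j - a - b + 1)/(j - 1).
    """
    b1, b2, b3 = beta123
    a = math.exp(b1 / 2)
    b = math.exp(b2 / 2)
    j = math.exp((b1 + b2 + b3) / 2)
    d = j - 1
    s = np.array([(a - 1) / d, (b - 1) / d, (j - a - b + 1) / d])
    # Partials: da/db1 = a/2, db/db2 = b/2, dj/dbk = j/2 for k in 1..3.
    dj = j / 2
    jac = np.empty((3, 3))
    jac[0] = [
        (a / 2) / d - (a - 1) * dj / d**2,
        -(a - 1) * dj / d**2,
        -(a - 1) * dj / d**2,
    ]
    jac[1] = [
        -(b - 1) * dj / d**2,
        (b / 2) / d - (b - 1) * dj / d**2,
        -(b - 1) * dj / d**2,
    ]
    jac[2] = [
        (dj - a / 2) / d - (j - a - b + 1) * dj / d**2,
        (dj - b / 2) / d - (j - a - b + 1) * dj / d**2,
        dj / d - (j - a - b + 1) * dj / d**2,
    ]
    return s, jac


def decompose_trend(fit: ITSFit, level: float = 0.95) -> TrendDecomposition:
    """Split the joint post-period 50-day effect into three additive shares.

    Converts exp(b1), exp(b2) and exp(b1+b2+b3) to risk ratios with the
    square-root approximation, then attributes the joint excess relative
    risk to the baseline trend, the policy, and their interaction (the
    relative excess risk due to interaction).  Standard errors come from
    the delta method through the full chain; p-values are one-sided tests
    of each share against zero.  Undefined when the joint risk ratio is
    not above 1.
    """
    if not fit.converged:
        raise ConvergenceError("cannot decompose a non-converged fit")
    beta = np.asarray(fit.beta)
    rr_joint = math.exp((beta[1] + beta[2] + beta[3]) / 2)
    if rr_joint <= 1:
        raise ValueError(
            "trend decomposition undefined: joint post-period risk ratio <= 1"
        )
    shares, jac = _shares_and_jacobian(beta[1:])
    vcov123 = fit.vcov_matrix[1:, 1:]
    cov_shares = jac @ vcov123 @ jac.T
    se = np.sqrt(np.clip(np.diag(cov_shares), 0, None))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    ci = tuple((float(s - z * e), float(s + z * e)) for s, e in zip(shares, se))
    p_one = tuple(float(stats.norm.sf(s / e)) if e > 0 else 0.0 for s, e in zip(shares, se))
    return TrendDecomposition(
        rr_time=math.exp(beta[1] / 2),
        rr_policy=math.exp(beta[2] / 2),
        rr_joint=rr_joint,
        share_baseline=float(shares[0]),
        share_policy=float(shares[1]),
        share_interaction=float(shares[2]),
        se=tuple(float(e) for e in se),
        ci=ci,
        p_one_sided=p_one,
    )


def predict_probability(
    fit: ITSFit, time: float, post: int, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Model probability at a design point, with a delta-method CI.

    The CI is computed on the logit scale and mapped through expit, so the
    bounds always lie in [0, 1].
    """
    if not fit.converged:
        raise ConvergenceError("cannot predict from a non-converged fit")
    x = np.array([1.0, time, float(post), time * float(post)])
    eta = float(x @ np.asarray(fit.beta))
    se = math.sqrt(float(x @ fit.vcov_matrix @ x))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return float(expit(eta)), (float(expit(eta - z * se)), float(expit(eta + z * se)))
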