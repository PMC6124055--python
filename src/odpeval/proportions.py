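"""Confidence intervals and tests for proportions.

Three procedures used throughout the reports:

* Wilson score intervals with continuity correction for binomial
  proportions (Newcombe's closed-form bounds);
* Sison–Glaz simultaneous confidence intervals for multinomial
  proportions, calibrated through the truncated-Poisson/Edgeworth
  coverage approximation;
* Pearson's chi-squared test of independence for 2x2 tables, without
  Yates continuity correction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BinomialCI",
    "MultinomialCI",
    "ChiSquareResult",
    "wilson_cc_interval",
    "sison_glaz_intervals",
    "pearson_chi2_2x2",
    "round_percent",
]


def round_percent(fraction: float) -> int:
    """Fraction -> integer percentage, rounding half away from zero."""
    return int(math.floor(abs(fraction) * 100 + 0.5)) * (1 if fraction >= 0 else -1)


@dataclass(frozen=True)
class BinomialCI:
    x: int
    n: int
    level: float
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.x / self.n

    def percent_bounds(self) -> tuple[int, int]:
        """Bounds as integer percentages, the display convention of the reports."""
        return round_percent(self.lower), round_percent(self.upper)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


@dataclass(frozen=True)
class MultinomialCI:
    counts: tuple[int, ...]
    n: int
    level: float
    c: int
    gamma: float
    intervals: tuple[tuple[float, float], ...]

    def percent_bounds(self) -> list[tuple[int, int]]:
        return [(round_percent(lo), round_percent(hi)) for lo, hi in self.intervals]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def wilson_cc_interval(x: int, n: int, level: float = 0.95) -> BinomialCI:
    """Continuity-corrected Wilson score interval for a binomial proportion.

    Uses Newcombe's closed-form bounds.  At x = 0 (resp. x = n) the lower
    (resp. upper) bound is pinned to 0 (resp. 1); both bounds are truncated
    to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    p = x / n
    if x == 0:
        lower = 0.0
    else:
        lower = (
            2 * n * p
            + z * z
            - 1
            - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
        ) / (2 * (n + z * z))
    if x == n:
        upper = 1.0
    else:
        upper = (
            2 * n * p
            + z * z
            + 1
            + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
        ) / (2 * (n + z * z))
    return BinomialCI(x=x, n=n, level=level, lower=max(0.0, lower), upper=min(1.0, upper))


def _sison_glaz_coverage(counts: np.ndarray, c: int) -> float:
    """Coverage probability nu(c) that every cell count lies within +/- c.

    Conditional-representation identity: a multinomial vector is a vector of
    independent Poissons conditioned on their sum.  Each Poisson(n_i) is
    truncated to [n_i - c, n_i + c]; the probability that the truncated sum
    equals n is approximated by an Edgeworth expansion (third and fourth
    cumulants), and the conditioning Poisson(n) mass at n is exact.
    """
    n = int(counts.sum())
    prod_p = 1.0
    mean_sum = 0.0
    k2 = k3 = k4 = 0.0
    for ni in counts:
        lo, hi = max(0, int(ni) - c), int(ni) + c
        ks = np.arange(lo, hi + 1)
        pm = stats.poisson.pmf(ks, ni)  # mu = 0 is degenerate at 0, handled by scipy
        total = pm.sum()
        prod_p *= total
        w = pm / total
        m = float((w * ks).sum())
        d = ks - m
        v = float((w * d**2).sum())
        mu3 = float((w * d**3).sum())
        mu4 = float((w * d**4).sum())
        mean_sum += m
        k2 += v
        k3 += mu3
        k4 += mu4 - 3 * v * v
    z = (n - mean_sum) / math.sqrt(k2)
    g1 = k3 / k2**1.5
    g2 = k4 / k2**2
    he3 = z**3 - 3 * z
    he4 = z**4 - 6 * z**2 + 3
    he6 = z**6 - 15 * z**4 + 45 * z**2 - 15
    f_e = (
        stats.norm.pdf(z)
        * (1 + g1 * he3 / 6 + g2 * he4 / 24 + g1 * g1 * he6 / 72)
        / math.sqrt(k2)
    )
    return f_e * prod_p / stats.poisson.pmf(n, n)


def sison_glaz_intervals(counts, level: float = 0.95) -> MultinomialCI:
    """Sison–Glaz simultaneous confidence intervals for multinomial proportions.

    Finds the smallest integer half-width ``c`` such that the approximate
    simultaneous coverage satisfies nu(c) < level <= nu(c + 1), interpolates
    a fractional adjustment ``gamma``, and returns intervals

        [p_i - c/n,  p_i + c/n + 2 gamma / n]

    truncated to [0, 1].  All cells share the same half-widths before
    truncation.
    """
    arr = np.asarray(counts, dtype=int)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-d vector of at least 2 category counts")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    n = int(arr.sum())
    if n < 1:
        raise ValueError("all-zero counts")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")

    c = 1
    nu_c = _sison_glaz_coverage(arr, c)
    if nu_c >= level:
        # Already covering at the smallest admissible half-width.
        gamma = 0.0
    else:
        while True:
            nu_next = _sison_glaz_coverage(arr, c + 1)
            if level <= nu_next:
                break
            c += 1
            nu_c = nu_next
            if c > n:
                raise RuntimeError("Sison–Glaz calibration failed to bracket the level")
        if nu_next == level:
            # Exact tie: resolve to the covering half-width with no adjustment.
            c += 1
            gamma = 0.0
        else:
            gamma = (level - nu_c) / (nu_next - nu_c)
    p_hat = arr / n
    half = c / n
    intervals = tuple(
        (max(0.0, p - half), min(1.0, p + half + 2 * gamma / n)) for p in p_hat
    )
    return MultinomialCI(
        counts=tuple(int(v) for v in arr),
        n=n,
        level=level,
        c=c,
        gamma=float(gamma),
        intervals=intervals,
    )


def pearson_chi2_2x2(table) -> ChiSquareResult:
    """Uncorrected Pearson chi-squared test of independence on a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (obs.sum(axis=0) <= 0).any() or (obs.sum(axis=1) <= 0).any():
        raise ValueError("both margins must be positive")
    statistic, p_value, df, _ = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(statistic), df=int(df), p_value=float(p_value))
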