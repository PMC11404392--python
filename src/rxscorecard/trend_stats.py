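"""Evaluation statistics: Poisson quarterly trend, pre/post chi-square,
Wilson proportion intervals, and the reporting `proportion` helper.

The trend model is a Poisson log-linear regression of quarterly prescription
counts on quarter index:

    log E[count_q] = beta0 + beta1 * q,        q = 0, 1, ..., n-1

fit by iteratively reweighted least squares (Fisher scoring, canonical log
link), with a Wald test on ``beta1``.  ``exp(beta1)`` is the quarterly rate
ratio; ``100 * (1 - exp(beta1))`` is the percent change per quarter (positive
for a declining series).  No exposure offset is used — the series is modelled
as raw division-level counts — and overdispersion is not corrected; both
choices are recorded in report metadata and noted as limitations.

The pre/post comparison pools the post-period quarters into a single 2x2
table (exceeding vs not, pre vs post) and applies Pearson's chi-square
without continuity correction.  Proportion confidence intervals are Wilson
score intervals; the method is pinned because it is well defined and testable
against its closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class TrendResult:
    beta0: float
    beta1: float
    pct_change_per_quarter: float
    se_beta1: float
    p_value: float
    n_quarters: int

    @property
    def rate_ratio(self) -> float:
        return math.exp(self.beta1)


@dataclass(frozen=True)
class PrePostComparison:
    pre_numerator: int
    pre_denominator: int
    post_numerator: int
    post_denominator: int
    pre_proportion: float          # percent
    post_proportion: float         # percent
    pre_ci: tuple[float, float]    # percent
    post_ci: tuple[float, float]   # percent
    chi2_stat: float
    p_value: float


def proportion(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with half-up rounding, as printed on the scorecards.

    ``proportion(386, 2034)`` -> ``19.0``.  Banker's rounding would silently
    disagree with the hand-rounded published tables, so half-up is pinned.
    """
    if denominator == 0:
        raise ZeroDivisionError("proportion with zero denominator")
    pct = (Decimal(str(numerator)) * 100) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def poisson_trend(counts: Sequence[float]) -> TrendResult:
    """Fit the quarterly log-linear Poisson trend by IRLS.

    Requires at least 3 quarters of non-negative counts, not all zero.
    Convergence: max absolute coefficient change < 1e-10, at most 50
    iterations; non-convergence raises with diagnostics.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("need at least 3 quarterly counts")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if not y.any():
        raise ValueError("all-zero count series has no trend")
    n = len(y)
    X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    beta = np.array([math.log(y.mean()), 0.0])
    for _ in range(50):
        mu = np.exp(X @ beta)
        W = X.T * mu            # X^T diag(mu)
        info = W @ X
        step = np.linalg.solve(info, X.T @ (y - mu))
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    else:
        raise RuntimeError(
            f"IRLS did not converge in 50 iterations (last step {step})")
    mu = np.exp(X @ beta)
    cov = np.linalg.inv((X.T * mu) @ X)
    se1 = math.sqrt(cov[1, 1])
    z = beta[1] / se1
    p = 2 * stats.norm.sf(abs(z))
    return TrendResult(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        pct_change_per_quarter=100.0 * (1.0 - math.exp(beta[1])),
        se_beta1=se1,
        p_value=float(p),
        n_quarters=n,
    )


def chisq_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the table
    [[a, b], [c, d]]; errors on a zero margin."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(stat), float(p)


def proportion_ci(numerator: int, denominator: int,
                  level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval, returned in percent."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    lo, hi = proportion_confint(numerator, denominator,
                                alpha=1 - level, method="wilson")
    # boundary cases are exact by definition; remove floating-point fuzz
    lo = 0.0 if numerator == 0 else float(lo)
    hi = 1.0 if numerator == denominator else float(hi)
    return 100.0 * lo, 100.0 * hi


def prepost_compare(pre_counts: tuple[int, int],
                    post_counts: Sequence[tuple[int, int]],
                    level: float = 0.95) -> PrePostComparison:
    """Compare an exceedance proportion before vs after the intervention.

    ``pre_counts`` is ``(numerator, denominator)`` for the baseline quarter;
    ``post_counts`` is one such pair per post-intervention quarter, pooled
    before testing.
    """
    if len(post_counts) < 1:
        raise ValueError("post period must pool at least one quarter")
    pre_n, pre_d = (int(v) for v in pre_counts)
    post_n = int(sum(n for n, _ in post_counts))
    post_d = int(sum(d for _, d in post_counts))
    stat, p = chisq_2x2(pre_n, pre_d - pre_n, post_n, post_d - post_n)
    return PrePostComparison(
        pre_numerator=pre_n, pre_denominator=pre_d,
        post_numerator=post_n, post_denominator=post_d,
        pre_proportion=100.0 * pre_n / pre_d,
        post_proportion=100.0 * post_n / post_d,
        pre_ci=proportion_ci(pre_n, pre_d, level),
        post_ci=proportion_ci(post_n, post_d, level),
        chi2_stat=stat, p_value=p,
    )
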