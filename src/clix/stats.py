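"""Rank-based statistics for the heterogeneity analysis.

Thin, validated wrappers around the standard tests (Spearman,
Kruskal-Wallis, Wilcoxon rank-sum, Fisher exact) plus two pieces that need
their own implementation: a residualized-rank partial Spearman correlation
and an exact conditional test for 2xK contingency tables.  Every operation
returns a :class:`StatResult` so downstream reporting is uniform.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConstantInputError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class StatResult:
    """One test: named statistic, estimate, two-sided p, and sample size."""

    statistic_name: str
    estimate: float
    p_value: float
    n: int
    groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0,1]")


def _check_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    if len(x) < min_n:
        raise ValidationError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with mid-rank ties and two-sided p."""
    x, y = _check_xy(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return StatResult("spearman_rho", float(rho), float(p), len(x))


def partial_spearman(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> StatResult:
    """Partial Spearman correlation of x and y adjusting for covariate z.

    All three vectors are rank-transformed (mid-ranks); the ranks of x and y
    are residualized on the ranks of z by least squares and the Pearson
    correlation of the residuals is returned, with a two-sided p on n-3
    degrees of freedom.  A constant z carries no information, so the plain
    Spearman correlation is returned (with a warning) in that case.
    """
    x, y = _check_xy(x, y, 4)
    z = np.asarray(z, dtype=float)
    if z.shape != x.shape:
        raise ValidationError("z must match x and y in length")
    if not np.all(np.isfinite(z)):
        raise ValidationError("inputs must be finite")
    if np.ptp(z) == 0:
        warnings.warn(
            "constant covariate: falling back to plain Spearman", stacklevel=2
        )
        res = spearman(x, y)
        return StatResult("partial_spearman_rho", res.estimate, res.p_value, res.n)
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    design = np.column_stack([np.ones_like(rz), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.ptp(res_x) == 0 or np.ptp(res_y) == 0:
        raise ConstantInputError("residual ranks are constant")
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    n = len(x)
    df = n - 3
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * math.sqrt(df / (1.0 - rho_c * rho_c))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult("partial_spearman_rho", rho, p, n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 1 for a in arrs):
        raise ValidationError("need >= 2 non-empty groups")
    total = sum(len(a) for a in arrs)
    if total < 5:
        raise ValidationError("need >= 5 observations in total")
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise ValidationError("inputs must be finite")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return StatResult("kruskal_wallis_H", 0.0, 1.0, total)
    h, p = sps.kruskal(*arrs)
    return StatResult("kruskal_wallis_H", float(h), float(p), total)


EXACT_WILCOXON_MAX_N = 8


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the smaller sample has at most
    ``EXACT_WILCOXON_MAX_N`` observations and there are no ties; otherwise
    the normal approximation with continuity and tie correction.  The
    estimate is the Mann-Whitney U of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("inputs must be finite")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = min(len(a), len(b)) <= EXACT_WILCOXON_MAX_N and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return StatResult(
        "wilcoxon_rank_sum_U", float(res.statistic), float(res.pvalue), len(combined)
    )


def _fisher_2xk_exact(table: np.ndarray) -> float:
    """Exact conditional p for a 2xK table: total probability of all tables
    with the observed margins whose probability does not exceed the observed
    one (Freeman-Halton)."""
    r1 = int(table[0].sum())
    cols = table.sum(axis=0).astype(int)
    n = int(table.sum())
    denom = comb(n, r1)

    def prob(first_row: tuple[int, ...]) -> float:
        num = 1
        for a_j, c_j in zip(first_row, cols):
            num *= comb(c_j, a_j)
        return num / denom

    p_obs = prob(tuple(int(v) for v in table[0]))
    total = 0.0
    ranges = [range(0, c + 1) for c in cols[:-1]]
    for partial in itertools.product(*ranges):
        last = r1 - sum(partial)
        if 0 <= last <= cols[-1]:
            p = prob(partial + (last,))
            if p <= p_obs * (1 + 1e-9):
                total += p
    return min(total, 1.0)


def fisher_exact(table) -> StatResult:
    """Fisher exact test for a 2x2 or 2xK table of counts.

    For 2x2 tables the estimate is the conditional maximum-likelihood odds
    ratio and the p-value the usual two-sided Fisher probability; for 2xK
    (K > 2) the p-value comes from full enumeration of tables with the
    observed margins and no single odds ratio is defined (estimate NaN).
    """
    t = np.asarray(table)
    if t.ndim != 2 or 2 not in t.shape:
        raise ValidationError("table must be 2xK or Kx2")
    if t.shape[0] != 2:
        t = t.T
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or np.any(t < 0):
            raise ValidationError("table entries must be non-negative integers")
        t = np.round(t).astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("table has a zero margin")
    n = int(t.sum())
    if t.shape[1] == 2:
        _, p = sps.fisher_exact(t, alternative="two-sided")
        or_cond = sps.contingency.odds_ratio(t, kind="conditional").statistic
        return StatResult("fisher_exact_or", float(or_cond), float(p), n)
    p = _fisher_2xk_exact(t)
    return StatResult("fisher_exact_2xk", float("nan"), p, n)


def mmse_decline(series: Sequence[tuple[float, float]]) -> float:
    """MMSE decline in points lost per year (positive = decline).

    The negated least-squares slope of score on time; at least two visits at
    strictly increasing times are required.
    """
    if len(series) < 2:
        raise InsufficientDataError("need >= 2 MMSE time points")
    t = np.asarray([p[0] for p in series], dtype=float)
    s = np.asarray([p[1] for p in series], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("MMSE times must be strictly increasing")
    slope = np.polyfit(t, s, 1)[0]
    return float(-slope)
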