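"""Rank-based statistical primitives shared by every pipeline stage.

Self-contained implementations of the Spearman correlation (plain and
covariate-adjusted), the two-sided Mann-Whitney U test, Benjamini-Hochberg
FDR q-values, and the linear-interpolation 75th percentile used for
co-abundance group profiles.  These are deliberately written from the
textbook definitions so that the heavier pipeline stages (module
enrichment, driver attribution) rest on a small, fully specified and
independently testable core rather than on any particular library's
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "CorrelationResult",
    "RankTestResult",
    "spearman_rho",
    "adjusted_spearman",
    "mann_whitney_u",
    "bh_fdr",
    "percentile_75",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A rank correlation: coefficient in [-1, 1], two-sided p, sample size."""

    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RankTestResult:
    """A two-sided Mann-Whitney U test result.

    ``method`` records whether the p-value came from the exact null
    distribution ("exact") or the tie-corrected normal approximation with
    continuity correction ("normal_tie_corrected").
    """

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero rank variance")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def _t_p_value(rho: float, df: int) -> float:
    """Two-sided p for a (partial) correlation via the t approximation."""
    if df <= 0:
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    return float(2.0 * t_dist.sf(abs(t), df))


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation with a t-approximation p-value.

    rho is the Pearson correlation of midranks; the p-value uses the
    t statistic with n - 2 degrees of freedom.  Constant input raises
    (``zero rank variance``) because ranks carry no information there.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rho = _pearson(rankdata(x), rankdata(y))
    return CorrelationResult(rho=rho, p_value=_t_p_value(rho, n - 2), n=n)


def adjusted_spearman(x, y, covariate) -> CorrelationResult:
    """Partial Spearman correlation of x and y controlling one covariate.

    All three vectors are midrank-transformed; rho is the first-order
    partial Pearson correlation of the ranks and the p-value uses n - 3
    degrees of freedom.  This is the "age adjusted" rank correlation used
    for diversity-phenotype and KO-phenotype associations.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    z = _as_1d(covariate, "covariate")
    if not (len(x) == len(y) == len(z)):
        raise ValueError("x, y and covariate must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations for an adjusted correlation")
    rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
    r_xy = _pearson(rx, ry)
    r_xz = _pearson(rx, rz)
    r_yz = _pearson(ry, rz)
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 1e-12:
        raise ValueError("covariate is collinear with x or y ranks")
    rho = float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(denom_sq), -1.0, 1.0))
    return CorrelationResult(rho=rho, p_value=_t_p_value(rho, n - 3), n=n)


def _u_distribution(n1: int, n2: int) -> np.ndarray:
    """Null probability mass of U for group sizes (n1, n2), no ties.

    Uses the classical recurrence obtained by conditioning on the group of
    the largest pooled observation: N(u; i, j) = N(u - j; i - 1, j) +
    N(u; i, j - 1), with N(u; 0, j) = N(u; i, 0) = [u == 0].
    """
    max_u = n1 * n2
    counts = np.zeros((n1 + 1, n2 + 1, max_u + 1), dtype=float)
    counts[0, :, 0] = 1.0
    counts[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            counts[i, j, :] = counts[i, j - 1, :]
            counts[i, j, j:] += counts[i - 1, j, : max_u + 1 - j]
    pmf = counts[n1, n2]
    return pmf / pmf.sum()


def mann_whitney_u(a, b, alternative: str = "two_sided") -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    U is computed from midrank sums.  When the pooled sample is small
    (n1 + n2 <= 16) and tie-free, the p-value is exact (full null
    distribution of U); otherwise a normal approximation with tie
    correction and a 0.5 continuity correction is used.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    has_ties = len(np.unique(pooled)) < n
    if n <= 16 and not has_ties:
        pmf = _u_distribution(n1, n2)
        u_int = int(round(u1))
        u_min = min(u_int, n1 * n2 - u_int)
        p = float(min(1.0, 2.0 * pmf[: u_min + 1].sum()))
        return RankTestResult(u_statistic=float(u_int), p_value=p, n1=n1, n2=n2, method="exact")
    p = _normal_approx_p(u1, n1, n2, pooled)
    return RankTestResult(
        u_statistic=float(u1), p_value=p, n1=n1, n2=n2, method="normal_tie_corrected"
    )


def _normal_approx_p(u1: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    """Two-sided normal approximation with tie correction and a 0.5
    continuity correction."""
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))
    var_u = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var_u <= 0:
        # all values identical: no evidence either way
        return 1.0
    z = max(0.0, (abs(u1 - mean_u) - 0.5)) / np.sqrt(var_u)
    return float(min(1.0, 2.0 * norm.sf(z)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics;
    monotone non-decreasing in sorted p and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any(np.isnan(p)):
        raise ValueError("p_values contain NaN")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def percentile_75(values) -> float:
    """Linear-interpolation 75th percentile: h = (n - 1) * 0.75."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if v.size == 0:
        raise ValueError("values must be non-empty")
    s = np.sort(v)
    h = (v.size - 1) * 0.75
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    if lo == hi:
        return float(s[lo])
    return float(s[lo] + (h - lo) * (s[hi] - s[lo]))
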