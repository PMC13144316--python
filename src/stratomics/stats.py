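"""Statistical primitives for cohort comparison.

Every routine here is implemented from first principles so it can be checked
against brute-force oracles (exhaustive enumeration of 2x2 tables, direct
tail summation, full permutation of rank labelings).  Conventions follow the
mainstream bioinformatics tooling ecosystem:

* two-sided Fisher p-values use the probability-mass definition (sum over
  tables at most as probable as the observed one, with a small relative
  tolerance on the comparison);
* Mann-Whitney uses average joint ranks, a tie-corrected normal
  approximation with continuity correction for large samples, and exact
  enumeration for small tie-free samples;
* odds ratios are unconditional cross-product ratios with zero cells
  reported as ``inf``/``nan`` rather than silently smoothed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp, ndtr
from scipy.stats import rankdata

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_two_sided",
    "bh_adjust",
    "mann_whitney_u",
    "wilcoxon_rank_sum",
    "hypergeom_upper_tail",
    "cosine_similarity",
    "nnls",
]

#: relative tolerance used when comparing hypergeometric point masses in the
#: two-sided Fisher test, absorbing floating-point noise
FISHER_MASS_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 comparison.

    ``a``/``b`` are events / non-events in group 1; ``c``/``d`` in group 2.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    odds_ratio: float  # may be inf; nan means undefined
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K, n)."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(K + 1)
        - gammaln(k + 1)
        - gammaln(K - k + 1)
        + gammaln(N - K + 1)
        - gammaln(n - k + 1)
        - gammaln(N - K - (n - k) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Unconditional cross-product ratio a*d / (b*c).

    Returns ``inf`` when only the denominator product is zero and ``nan``
    (undefined) when both products vanish.
    """
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of every table with the
    same margins whose point mass is at most the observed one (relative
    tolerance ``FISHER_MASS_RTOL``).  A degenerate table with an all-zero
    margin yields p = 1 and an undefined odds ratio.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("each group must contain at least one observation")
    N = table.n
    K = a + c  # events overall
    n = a + b  # size of group 1
    if K == 0 or K == N:
        # no events (or all events) anywhere: single attainable table
        return TestResult(statistic=1.0, p_value=1.0, odds_ratio=odds_ratio(table), method="fisher_exact")
    lo = max(0, n - (N - K))
    hi = min(n, K)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, N, K, n)
    log_obs = float(logp[a - lo])
    keep = logp <= log_obs + math.log1p(FISHER_MASS_RTOL)
    p = float(np.exp(logsumexp(logp[keep])))
    p = min(1.0, p)
    return TestResult(statistic=math.exp(log_obs), p_value=p, odds_ratio=odds_ratio(table), method="fisher_exact")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _exact_mw_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of all labelings."""
    pooled = np.concatenate([x, y])
    n = pooled.size
    nx = x.size
    mu = nx * y.size / 2.0
    dev = abs(u_obs - mu)
    ranks = rankdata(pooled)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), nx):
        rx = ranks[list(idx)].sum()
        u = rx - nx * (nx + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / total


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "normal", "auto"] = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``auto`` uses exact enumeration for small tie-free samples
    (n_x + n_y <= 12) and otherwise a tie-corrected normal approximation
    with continuity correction.  All-tied data yield p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if mode == "auto":
        mode = "exact" if (nx + ny <= 12 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        p = _exact_mw_p(x, y, u)
        return TestResult(statistic=u, p_value=min(1.0, p), odds_ratio=math.nan, method="mann_whitney_exact")
    if mode != "normal":
        raise ValueError(f"unknown mode: {mode!r}")

    n = nx + ny
    mu = nx * ny / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(statistic=u, p_value=1.0, odds_ratio=math.nan, method="mann_whitney_normal")
    diff = abs(u - mu) - 0.5  # continuity correction
    z = max(diff, 0.0) / math.sqrt(var)
    p = min(1.0, 2.0 * float(ndtr(-z)))
    return TestResult(statistic=u, p_value=p, odds_ratio=math.nan, method="mann_whitney_normal")


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "normal", "auto"] = "auto",
) -> TestResult:
    """Alias of :func:`mann_whitney_u` (identical statistic and p-value)."""
    return mann_whitney_u(x, y, mode=mode)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    if not (lo <= k <= hi):
        raise ValueError(f"k={k} outside support [{lo}, {hi}]")
    support = np.arange(k, hi + 1)
    return float(min(1.0, np.exp(logsumexp(_log_hypergeom_pmf(support, N, K, n)))))


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine of the angle between two non-negative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same shape")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def nnls(A: np.ndarray, b: np.ndarray, max_iter: int | None = None, tol: float = 1e-12) -> np.ndarray:
    """Non-negative least squares by the Lawson-Hanson active-set method.

    Minimizes ||A x - b||_2 subject to x >= 0.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or b.ndim != 1 or A.shape[0] != b.size:
        raise ValueError(f"dimension mismatch: A {A.shape}, b {b.shape}")
    m, s = A.shape
    if max_iter is None:
        max_iter = 3 * s
    x = np.zeros(s)
    passive = np.zeros(s, dtype=bool)
    w = A.T @ (b - A @ x)
    it = 0
    while (not passive.all()) and np.any(w[~passive] > tol):
        j = int(np.argmax(np.where(passive, -np.inf, w)))
        passive[j] = True
        while True:
            it += 1
            if it > max_iter * 10:
                break
            z = np.zeros(s)
            cols = np.flatnonzero(passive)
            z[cols], *_ = np.linalg.lstsq(A[:, cols], b, rcond=None)
            if np.all(z[cols] > tol):
                x = z
                break
            neg = cols[z[cols] <= tol]
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = x[neg] / (x[neg] - z[neg])
            alpha = np.min(alphas)
            x = x + alpha * (z - x)
            passive[np.abs(x) <= tol] = False
            x[~passive] = 0.0
        w = A.T @ (b - A @ x)
        if it > max_iter * 10:
            break
    return np.clip(x, 0.0, None)
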