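"""Two-sample tests for small cohorts: Student's t and the exact Mann-Whitney U.

With five animals per group, asymptotic rank tests are unreliable; the exact
Mann-Whitney p-value is computed by enumerating every assignment of the
pooled observations to the two groups (ties included, since the enumeration
permutes the actual values).  For complete separation at n = 5 vs 5 the
two-sided exact p is 2/252 ~ 0.0079, the smallest attainable.  Above a
combined n of 20 a tie-corrected normal approximation with continuity
correction takes over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "students_t", "mann_whitney", "holm_adjust", "EXACT_LIMIT"]

EXACT_LIMIT = 20  # combined sample size up to which exact enumeration is default


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_two_sided: float
    n_a: int
    n_b: int
    df: float | None = None
    degenerate: bool = False
    tie_note: bool = False


def students_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-tailed two-sample t-test (pooled variance by default, Welch optional).

    Zero pooled variance is degenerate: p = 1 with equal means, the p -> 0
    limit with unequal means; both are flagged rather than raised.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    method = "welch_t" if welch else "students_t"
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            p = 1.0 if ma == mb else 0.0
            return TestResult(method, 0.0 if ma == mb else math.inf * np.sign(ma - mb),
                              p, na, nb, df=float("nan"), degenerate=True)
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        df = float(na + nb - 2)
        if sp2 == 0:
            p = 1.0 if ma == mb else 0.0
            return TestResult(method, 0.0 if ma == mb else math.inf * np.sign(ma - mb),
                              p, na, nb, df=df, degenerate=True)
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(method, float(t), float(min(p, 1.0)), na, nb, df=float(df))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a from midranks of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    mode: Literal["auto", "exact", "normal_approx"] = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact mode enumerates all C(n_a + n_b, n_a) assignments of the observed
    pooled values (ties handled by enumerating the actual values) and takes
    the probability of |U - n_a n_b / 2| at least as extreme as observed.
    ``auto`` uses the exact test up to a combined n of 20, the tie-corrected
    normal approximation with continuity correction beyond.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    if mode == "auto":
        mode = "exact" if na + nb <= EXACT_LIMIT else "normal_approx"

    u_obs = _u_statistic(a, b)
    mu = na * nb / 2.0
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if mode == "exact":
        ranks = sps.rankdata(pooled)
        offs = na * (na + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        n_total = 0
        n_extreme = 0
        for idx in combinations(range(na + nb), na):
            u = ranks[list(idx)].sum() - offs
            n_total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                n_extreme += 1
        p = n_extreme / n_total
        method = "mann_whitney_exact"
    else:
        n = na + nb
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return TestResult("mann_whitney_normal", u_obs, 1.0, na, nb,
                              degenerate=True, tie_note=has_ties)
        z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
        z = max(z, 0.0)
        p = 2.0 * sps.norm.sf(z)
        method = "mann_whitney_normal"
    return TestResult(method, u_obs, float(min(p, 1.0)), na, nb, tie_note=has_ties)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj
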