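"""Two-sample tests and standard-error propagation used across the package.

The group comparisons mirror common practice in plot-based ecology: a
two-sample t test (Welch by default, pooled optionally) alongside a
Wilcoxon/Mann-Whitney rank-sum test.  For small samples the rank-sum p-value
is computed by full enumeration over rank assignments, which stays exact in
the presence of ties; larger samples use the normal approximation with tie
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "rank_sum_test",
    "signed_rank_test",
    "t_test",
    "propagate_se",
]

# full enumeration is used when C(n1+n2, n1) does not exceed this
_EXACT_LIMIT = 200_000


@dataclass
class TestResult:
    """Outcome of a two-sample location test."""

    test: str
    statistic: float
    p_value: float
    df: float | None = None
    method: str | None = None

    def __iter__(self):  # allows tuple-unpacking (stat, p)
        yield self.statistic
        yield self.p_value


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum W of the first group.

    Enumerates every assignment of the pooled (mid)ranks to group 1 and
    doubles the smaller tail, clipping at 1.  Midranks make the enumeration
    valid under ties.
    """
    total = math.comb(len(ranks), n1)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(len(ranks)), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def rank_sum_test(x, y, exact: str = "auto") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Parameters
    ----------
    x, y : array-like
        The two independent samples.
    exact : {"auto", "always", "never"}
        "auto" enumerates all rank assignments when feasible (small n);
        otherwise a tie-corrected normal approximation is used.

    Returns
    -------
    TestResult
        statistic is the Mann-Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0

    feasible = math.comb(n1 + n2, n1) <= _EXACT_LIMIT
    if exact == "always" or (exact == "auto" and feasible):
        p = _exact_rank_sum_p(ranks, n1, w)
        method = "exact enumeration"
    else:
        # normal approximation with tie correction
        n = n1 + n2
        mu = n1 * (n1 + 1 + n2) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (w - mu) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
        method = "normal approximation"
    return TestResult("rank-sum", u, p, method=method)


def signed_rank_test(x, y) -> TestResult:
    """Wilcoxon signed-rank test on paired samples (two-sided).

    Provided for parity with analyses that treat the two samples as paired;
    requires equal lengths.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("signed-rank test requires paired samples of equal length")
    d = x - y
    if np.allclose(d, 0):
        return TestResult("signed-rank", 0.0, 1.0, method="degenerate (all ties)")
    res = sps.wilcoxon(x, y)
    return TestResult("signed-rank", float(res.statistic), float(res.pvalue))


def t_test(x, y, pooled: bool = False) -> TestResult:
    """Two-sample t test, two-sided; Welch by default.

    With ``pooled=True`` the classical equal-variance test is used
    (df = n1 + n2 - 2); Welch uses the Satterthwaite df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t test requires at least two observations per group")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    if pooled:
        df = x.size + y.size - 2.0
    else:
        v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (v1 + v2) ** 2 / (
            v1**2 / (x.size - 1) + v2**2 / (y.size - 1)
        )
    name = "t (pooled)" if pooled else "t (Welch)"
    return TestResult(name, float(res.statistic), float(res.pvalue), df=float(df))


def propagate_se(terms) -> tuple[float, float]:
    """Sum independent (value, SE) terms; SE combined in quadrature.

    Parameters
    ----------
    terms : iterable of (float, float)
        Values with their standard errors (SE >= 0).

    Returns
    -------
    (sum, se) : tuple of float
        Sum of the values and sqrt(sum of squared SEs).
    """
    values, ses = [], []
    for v, se in terms:
        if se < 0:
            raise ValueError(f"negative SE {se} in propagation")
        values.append(float(v))
        ses.append(float(se))
    return float(np.sum(values)), float(np.sqrt(np.sum(np.square(ses))))
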