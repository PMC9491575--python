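"""Shared statistical primitives: BH adjustment, exact r×c Fisher test,
Wilcoxon rank tests.

The r×c Fisher test enumerates all contingency tables with the observed
margins (depth-first over the free cells) and sums the hypergeometric
probabilities of tables no more probable than the observed one — the
probability-mass two-sided definition, as R's ``fisher.test`` uses.
Cohort-scale tables (total ≤ 200) make exact enumeration feasible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

#: relative tolerance for the "no more probable" comparison on float masses
_MASS_RTOL = 1e-7

#: largest table total for which exact r×c enumeration is attempted
_MAX_TOTAL = 200


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    q_i = min over j with p_j >= p_i of (m * p_j / rank_j), capped at 1;
    ties and order are preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# exact r x c Fisher test


def _log_table_prob(table: np.ndarray, lognorm: float) -> float:
    # log P(table | margins) = [Π r_i! Π c_j! / (N! Π a_ij!)]
    return lognorm - gammaln(table + 1).sum()


def fisher_exact_rxc(table) -> TestResult:
    """Two-sided exact Fisher test for an r×c table of nonnegative integers.

    The p-value is the total conditional probability of all tables with the
    observed margins whose probability does not exceed the observed table's
    (within relative tolerance 1e-7).
    """
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.issubdtype(t.dtype, np.floating) and np.allclose(t, np.round(t)) and np.all(t >= 0):
            t = np.round(t).astype(int)
        else:
            raise ValueError("table cells must be nonnegative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("all row and column margins must be positive")
    total = int(t.sum())
    if total > _MAX_TOTAL:
        raise ValueError(
            f"exact infeasible: table total {total} exceeds {_MAX_TOTAL}"
        )
    lognorm = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(total + 1)
    obs_logp = _log_table_prob(t, lognorm)
    cutoff = obs_logp + np.log1p(_MASS_RTOL)

    r, c = t.shape
    p_sum = 0.0
    work = np.zeros((r, c), dtype=int)

    def fill(i: int, j: int, row_left: np.ndarray, col_left: np.ndarray) -> None:
        nonlocal p_sum
        if i == r - 1:
            # last row forced by the column margins (nonnegative by construction)
            work[i, :] = col_left
            logp = _log_table_prob(work, lognorm)
            if logp <= cutoff:
                p_sum += float(np.exp(logp))
            return
        if j == c - 1:
            # last column of this row forced by the row margin
            v = row_left[i]
            if v > col_left[j]:
                return
            work[i, j] = v
            rl = row_left.copy()
            rl[i] = 0
            cl = col_left.copy()
            cl[j] -= v
            fill(i + 1, 0, rl, cl)
            return
        hi = min(row_left[i], col_left[j])
        for v in range(hi + 1):
            work[i, j] = v
            rl = row_left.copy()
            rl[i] -= v
            cl = col_left.copy()
            cl[j] -= v
            fill(i, j + 1, rl, cl)

    fill(0, 0, rows.copy(), cols.copy())
    return TestResult(
        statistic=float(np.exp(obs_logp)),
        p_value=min(p_sum, 1.0),
        method="fisher_exact_rxc",
    )


# ---------------------------------------------------------------------------
# Wilcoxon tests


def wilcoxon_rank_sum(x, y, exact_below: int = 50) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution when the combined sample size is below
    ``exact_below`` and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size + y.size <= exact_below and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"wilcoxon_rank_sum_{method}",
    )


def wilcoxon_signed_rank(d, exact_below: int = 50) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's convention).  If every
    difference is zero the test is degenerate and p = 1 by convention.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("differences must be nonempty")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="wilcoxon_signed_rank_degenerate")
    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    if nonzero.size <= exact_below and not has_ties:
        mode = "exact"
    else:
        mode = "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=(mode == "approx"),
                         alternative="two-sided", method=mode)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"wilcoxon_signed_rank_{mode}",
    )
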