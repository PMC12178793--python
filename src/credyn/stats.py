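"""Nonparametric test battery: paired Friedman test, two-sample KS test, stars.

These are the two tests used throughout the analysis: the Friedman test for
paired per-element signal across the three damage timepoints, and the
unpaired two-sample Kolmogorov-Smirnov test for comparing element groups.
Both provide an exact small-sample path (full enumeration) and the standard
large-sample approximation, with the path recorded in the result.

Friedman statistic (tie-corrected chi-square form), for an n x k matrix of
within-row mid-ranks with column rank sums R_j::

    Q = [ 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1) ] / C
    C = 1 - sum(t^3 - t) / (n k (k^2 - 1))        over all within-row tie groups

If every row is fully tied, C = 0 and Q is defined as 0 with p = 1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

logger = logging.getLogger(__name__)

__all__ = ["TestResult", "friedman", "ks2", "stars"]

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    """Map a p-value to the significance-star convention.

    Strict inequalities: p < 0.05 -> ``*``, < 0.01 -> ``**``, < 0.001 ->
    ``***``, < 0.0001 -> ``****``; anything else is ``ns`` (so p = 0.05 is ns).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of [0, 1]: {p}")
    for cut, label in _STAR_THRESHOLDS:
        if p < cut:
            return label
    return "ns"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def stars(self) -> str:
        return stars(self.p_value)


# ---------------------------------------------------------------------------
# Friedman


def _friedman_q(rank_sums: np.ndarray, n: int, k: int, c: float) -> float:
    q_num = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    return q_num / c


def friedman(data, exact_n_max: int = 6) -> TestResult:
    """Paired Friedman test on an n x k matrix (rows = subjects, cols = conditions).

    Rows are ranked with mid-rank ties and the tie-corrected chi-square
    statistic is computed.  For n <= ``exact_n_max`` the p-value is exact,
    from enumeration of all (k!)^n equally likely within-row orderings;
    otherwise it is the chi-square upper tail with k - 1 degrees of freedom.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D matrix (rows = paired subjects)")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    if k < 2:
        raise ValueError("need at least 2 columns")
    if not np.isfinite(x).all():
        raise ValueError("data must be finite with no missing values")

    ranks = rankdata(x, axis=1)  # mid-ranks within rows
    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    c = 1.0 - tie_term / (n * k * (k**2 - 1))
    if c <= 0.0:  # every row fully tied
        return TestResult(0.0, 1.0, "friedman_chi2", df=k - 1)

    q = _friedman_q(ranks.sum(axis=0), n, k, c)

    if n <= exact_n_max:
        # all k! orderings of each row's mid-rank vector, kept with
        # multiplicity so tied rows stay uniformly weighted; tie structure
        # (and hence C) is permutation-invariant
        perm_idx = list(itertools.permutations(range(k)))
        row_perms = [np.asarray([r[list(p)] for p in perm_idx]) for r in ranks]
        sums = row_perms[0].astype(float)
        for perms in row_perms[1:]:
            sums = (sums[:, None, :] + perms[None, :, :]).reshape(-1, k)
        q_all = (
            12.0 / (n * k * (k + 1)) * np.sum(sums**2, axis=1) - 3.0 * n * (k + 1)
        ) / c
        p = float(np.mean(q_all >= q - 1e-12))
        return TestResult(float(q), min(p, 1.0), "friedman_exact", df=k - 1)

    p = float(chi2.sf(q, k - 1))
    return TestResult(float(q), min(max(p, 0.0), 1.0), "friedman_chi2", df=k - 1)


# ---------------------------------------------------------------------------
# Two-sample Kolmogorov-Smirnov


def _ks_statistic_int(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """D and its integer form max |i*n - j*m| over the merged ordering."""
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    labels = np.concatenate([np.zeros(m, dtype=int), np.ones(n, dtype=int)])
    order = np.argsort(pooled, kind="stable")
    i = j = 0
    best = 0
    sorted_vals = pooled[order]
    sorted_lab = labels[order]
    idx = 0
    while idx < m + n:
        v = sorted_vals[idx]
        # advance through all pooled values equal to v before evaluating,
        # so ties never contribute a spurious intermediate deviation
        while idx < m + n and sorted_vals[idx] == v:
            if sorted_lab[idx] == 0:
                i += 1
            else:
                j += 1
            idx += 1
        best = max(best, abs(i * n - j * m))
    return best / (m * n), best


def _ks_exact_p(m: int, n: int, d_int: int) -> float:
    """Exact P(max deviation >= d_int) over all C(m+n, n) tie-free orderings.

    Lattice-path count: paths from (0,0) to (m,n) keeping |i*n - j*m| < d_int
    are the orderings with D strictly below the observed value.
    """
    if d_int <= 0:
        return 1.0
    # DP over columns of the lattice, exact integer arithmetic
    prev = [0] * (n + 1)
    prev[0] = 1
    for j in range(1, n + 1):
        prev[j] = prev[j - 1] if abs(0 * n - j * m) < d_int else 0
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        cur[0] = prev[0] if abs(i * n) < d_int else 0
        for j in range(1, n + 1):
            if abs(i * n - j * m) < d_int:
                cur[j] = cur[j - 1] + prev[j]
        prev = cur
    total = math.comb(m + n, n)
    return 1.0 - prev[n] / total


def _ks_asymptotic_p(d: float, m: int, n: int) -> float:
    if d <= 0.0:
        return 1.0
    en = math.sqrt(m * n / (m + n))
    e = (en + 0.12 + 0.11 / en) * d
    total = 0.0
    for j in range(1, 1001):
        term = 2.0 * (-1) ** (j - 1) * math.exp(-2.0 * j * j * e * e)
        total += term
        if abs(term) < 1e-10:
            break
    return min(max(total, 0.0), 1.0)


def ks2(x, y, exact_total_max: int = 20) -> TestResult:
    """Unpaired two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs.  When
    m + n <= ``exact_total_max`` and the pooled sample is tie-free, the
    p-value is exact over all C(m+n, n) orderings; otherwise the standard
    asymptotic series is used (with a logged note if ties forced the
    fallback).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = xa.size, ya.size
    d, d_int = _ks_statistic_int(xa, ya)

    if m + n <= exact_total_max:
        pooled = np.concatenate([xa, ya])
        if np.unique(pooled).size == pooled.size:
            return TestResult(d, _ks_exact_p(m, n, d_int), "ks_exact")
        logger.info("pooled ties present; falling back to asymptotic KS p-value")
    return TestResult(d, _ks_asymptotic_p(d, m, n), "ks_asymptotic")
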