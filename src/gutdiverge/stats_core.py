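"""Exact overlap statistics for gene-set comparisons.

Every downstream stage of the pipeline — tissue-enrichment calling,
ortholog-level conservation, gene-family screens, pathogen-response
overlaps — reduces to the same question: is the observed intersection of
two gene sets within a finite universe larger (or smaller) than expected
under independence?  The answer is the tail probability of a
hypergeometric distribution, i.e. a one-sided Fisher exact test on the
2x2 contingency table.

The tail is computed in log-space with the pmf ratio recurrence

    pmf(k+1) / pmf(k) = (K-k)(n-k) / ((k+1)(N-K-n+k+1))

so that genome-scale tables (N in the millions of reads) neither
overflow nor underflow.  The summation terminates early once the
remaining geometric-series bound is negligible relative to the
accumulated sum, keeping the result exact to floating point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapStats",
    "hypergeom_pmf",
    "hypergeom_upper_tail",
    "hypergeom_lower_tail",
    "overlap_test",
    "overlap_stats_from_counts",
    "bh_adjust",
    "log_correlation",
]

# Relative truncation tolerance for the tail summation.  The geometric
# remainder bound must fall below this fraction of the running sum.
_TAIL_EPS = 1e-17


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if N <= 0:
        raise ValueError(f"universe size N must be > 0, got {N}")
    if K > N or n > N:
        raise ValueError(f"set sizes must not exceed the universe: K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K, n) = {min(K, n)}")


def _log_binom(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def _log_pmf(k: int, K: int, n: int, N: int) -> float:
    return _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n).

    Exposed mainly so the full-support normalisation (sum over k equals 1)
    can be asserted independently of the tail routines.
    """
    _validate_counts(k, K, n, N)
    if k < max(0, K + n - N):
        return 0.0
    return math.exp(_log_pmf(k, K, n, N))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    This is the one-sided (enrichment-direction) Fisher exact test for a
    2x2 table with margins K, n in a universe of N.

    Parameters
    ----------
    k : observed overlap count.
    K : size of the first set within the universe.
    n : size of the second set (number of draws).
    N : universe size.
    """
    _validate_counts(k, K, n, N)
    if n < K:
        # the distribution is symmetric in (K, n); canonicalise so the
        # swap-invariance of overlap tests holds exactly, not just to fp
        K, n = n, K
    k_min = max(0, K + n - N)
    k_max = min(K, n)
    if k <= k_min:
        return 1.0
    log_term = _log_pmf(k, K, n, N)
    log_total = log_term
    for j in range(k, k_max):
        log_term += math.log((K - j) * (n - j)) - math.log(
            (j + 1) * (N - K - n + j + 1)
        )
        if log_term > log_total:
            log_total = log_term + math.log1p(math.exp(log_total - log_term))
        else:
            log_total = log_total + math.log1p(math.exp(log_term - log_total))
        nxt = j + 1
        if nxt < k_max:
            ratio = ((K - nxt) * (n - nxt)) / ((nxt + 1) * (N - K - n + nxt + 1))
            if ratio < 1.0:
                # remaining tail <= term * ratio / (1 - ratio)
                rel = math.exp(log_term - log_total)
                if rel * ratio / (1.0 - ratio) < _TAIL_EPS:
                    break
    return min(1.0, math.exp(log_total))


def hypergeom_lower_tail(k: int, K: int, n: int, N: int) -> float:
    """Lower tail P(X <= k): the one-sided depletion-direction exact test.

    Uses the reflection X' = n - X ~ Hypergeometric(N, N-K, n), so that
    P(X <= k) = P(X' >= n - k) and the stable upper-tail summation is
    reused verbatim.
    """
    _validate_counts(k, K, n, N)
    return hypergeom_upper_tail(n - k, N - K, n, N)


@dataclass
class OverlapStats:
    """A 2x2 gene-set overlap within a finite universe.

    Attributes
    ----------
    k : observed overlap count.
    K : size of set 1 within the universe.
    n : size of set 2 within the universe.
    N : universe size.
    expected : K*n/N, the overlap expected under independence.
    fold : k/expected (0 when k=0; NaN and ``fold_defined=False`` when
        expected=0).
    p_value : one-sided exact tail probability (direction per the test
        that produced this object).
    q_value : optional multiplicity-adjusted p-value.
    """

    k: int
    K: int
    n: int
    N: int
    expected: float
    fold: float
    p_value: float
    q_value: float | None = None
    fold_defined: bool = True
    alternative: str = "greater"

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "K": self.K,
            "n": self.n,
            "N": self.N,
            "expected": self.expected,
            "fold": self.fold,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "fold_defined": self.fold_defined,
            "alternative": self.alternative,
        }


def overlap_stats_from_counts(
    k: int, K: int, n: int, N: int, alternative: str = "greater"
) -> OverlapStats:
    """Build an :class:`OverlapStats` directly from the four counts."""
    _validate_counts(k, K, n, N)
    expected = K * n / N
    if expected > 0:
        fold = k / expected
        fold_defined = True
    else:
        fold = math.nan
        fold_defined = False
    if k == 0:
        fold = 0.0 if fold_defined else fold
    if alternative == "greater":
        p = hypergeom_upper_tail(k, K, n, N)
    elif alternative == "less":
        p = hypergeom_lower_tail(k, K, n, N)
    elif alternative == "two-sided":
        # sum of all pmf values no larger than pmf(k); kept behind a flag,
        # the enrichment screens are directional by design
        pk = hypergeom_pmf(k, K, n, N)
        p = sum(
            hypergeom_pmf(j, K, n, N)
            for j in range(max(0, K + n - N), min(K, n) + 1)
            if hypergeom_pmf(j, K, n, N) <= pk * (1 + 1e-12)
        )
        p = min(1.0, p)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return OverlapStats(
        k=k, K=K, n=n, N=N, expected=expected, fold=fold,
        p_value=p, fold_defined=fold_defined, alternative=alternative,
    )


def overlap_test(
    set1: Iterable[str],
    set2: Iterable[str],
    universe: Iterable[str],
    alternative: str = "greater",
) -> OverlapStats:
    """Exact test of the overlap between two gene sets in a universe.

    Members of either set that fall outside the universe are dropped
    (and logged) before counting: published gene sets routinely carry
    retired identifiers.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    s1, s2 = set(set1), set(set2)
    out1, out2 = len(s1 - uni), len(s2 - uni)
    if out1 or out2:
        logger.info(
            "overlap_test: dropped %d/%d ids outside the universe", out1, out2
        )
    s1 &= uni
    s2 &= uni
    return overlap_stats_from_counts(
        k=len(s1 & s2), K=len(s1), n=len(s2), N=len(uni), alternative=alternative
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> float:
    """Correlation between two paired expression vectors.

    Pearson is computed on log10(value + 1), the usual display transform
    for FPKM scatter plots; Spearman is rank-based and applied to the raw
    values.  Pairs where both values are zero are retained.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("expression values must be non-negative")
    if method == "pearson":
        return float(_scipy_stats.pearsonr(np.log10(x + 1), np.log10(y + 1)).statistic)
    if method == "spearman":
        return float(_scipy_stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
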