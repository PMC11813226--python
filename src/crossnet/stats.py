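"""Shared statistical kernels.

Every hypergeometric overlap p-value and every Benjamini-Hochberg
adjustment in the package goes through the two functions defined here, so
that enrichment, reversal accounting and network edge filtering are
mutually consistent.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns q-values in the original order: q_(i) = min_{j>=i} ( m * p_(j) / j )
    clipped to 1. NaN inputs propagate as NaN and are excluded from m.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    q[ok] = out
    return q


def _log_hypergeom_pmf(k, N, K, n):
    """log P[X = k] for X ~ Hypergeometric(N, K, n)."""
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail overlap probability P[X >= k], X ~ Hypergeometric(N, K, n).

    The population has N items of which K belong to the category; n items
    are drawn without replacement; k is the observed overlap. Summation is
    done in log space for numerical stability at large N.

    Raises ``ValueError`` for impossible configurations
    (k > min(K, n), K > N, n > N, negative counts).
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if min(k, K, n, N) < 0 or K > N or n > N:
        raise ValueError(f"impossible hypergeometric configuration k={k} K={K} n={n} N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k <= max(0, K + n - N):
        return 1.0
    hi = min(K, n)
    ks = np.arange(k, hi + 1)
    logp = _log_hypergeom_pmf(ks, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def jaccard(a, b) -> float:
    """Jaccard similarity |a ∩ b| / |a ∪ b| of two gene-id sets (0 if both empty)."""
    a, b = set(a), set(b)
    u = a | b
    if not u:
        return 0.0
    return len(a & b) / len(u)


def format_percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Render 100 * numerator/denominator rounded to ``decimals`` places.

    ``decimals=0`` gives the integer-percent rendering used in some report
    styles. Raises on a zero denominator (callers report not-applicable).
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for empty denominator")
    return round(100.0 * numerator / denominator, decimals)
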