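"""Exact-test statistics shared across the pipeline.

The differential caller applies Fisher's exact test to one 2×2 read-count
table per sliding window and per cytosine, which at genome scale means
hundreds of thousands of tables.  ``fisher_exact_vec`` evaluates the
two-sided p-value for whole arrays of tables at once by enumerating each
table's hypergeometric support in a single flat pass; the scalar wrapper
delegates to scipy.  Benjamini–Hochberg adjustment comes from statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

# Relative tolerance used when deciding whether an outcome is "as extreme as"
# the observed one; matches the convention of common exact-test routines.
_REL_TOL = 1e-7


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    Values are clipped at 1 with monotonicity enforced.  Raises ``ValueError``
    for p-values outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a single 2×2 table of counts."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table entries must be nonnegative")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def _log_pmf(x, r1, r2, c1, n):
    """log hypergeometric pmf of x successes in column 1 given table margins."""
    return (
        gammaln(r1 + 1)
        - gammaln(x + 1)
        - gammaln(r1 - x + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - x + 1)
        - gammaln(r2 - c1 + x + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_vec(a, b, c, d, chunk_elements: int = 8_000_000) -> np.ndarray:
    """Two-sided Fisher exact p-values for arrays of 2×2 tables ((a,b),(c,d)).

    Each table's full hypergeometric support is enumerated; the p-value is
    the sum of point masses not exceeding the observed one (within a small
    relative tolerance).  Tables are processed in chunks bounded by
    ``chunk_elements`` enumerated outcomes to cap memory.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("table entries must be nonnegative")

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = np.maximum(0, c1 - r2)
    hi = np.minimum(c1, r1)
    lens = hi - lo + 1

    out = np.ones(a.shape, dtype=float)
    log_tol = np.log1p(_REL_TOL)

    start = 0
    ntab = a.size
    while start < ntab:
        stop = start
        total = 0
        while stop < ntab and total + lens[stop] <= chunk_elements:
            total += lens[stop]
            stop += 1
        if stop == start:  # single huge table
            stop = start + 1
            total = int(lens[start])
        sl = slice(start, stop)
        ln = lens[sl]
        idx = np.repeat(np.arange(stop - start), ln)
        offsets = np.concatenate([[0], np.cumsum(ln)[:-1]])
        x = np.arange(total) - np.repeat(offsets, ln) + lo[sl][idx]

        lp = _log_pmf(x, r1[sl][idx], r2[sl][idx], c1[sl][idx], n[sl][idx])
        lp_obs = _log_pmf(a[sl], r1[sl], r2[sl], c1[sl], n[sl])
        mask = lp <= lp_obs[idx] + log_tol
        p = np.bincount(
            idx[mask], weights=np.exp(lp[mask]), minlength=stop - start
        )
        out[sl] = np.clip(p, np.finfo(float).tiny, 1.0)
        start = stop

    # degenerate tables (an empty margin) carry no information
    out[n == 0] = 1.0
    return out


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    The standard over-representation p-value: the chance of seeing at least
    ``k`` annotated genes in a draw of ``n`` from a universe of ``N`` genes
    of which ``K`` carry the annotation.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got N={N} K={K} n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k} K={K} n={n}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))
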