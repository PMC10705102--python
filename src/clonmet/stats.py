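"""Core statistical primitives: Fisher exact test, BH FDR, ordered-trend test.

These are the building blocks shared by the variant filter, the
clonal-selection test and the cohort enrichment test.  The Fisher test
is exposed both as a scalar call and as a batch routine that groups
tables by their margins so that large variant tables are tested in one
vectorized pass per margin configuration.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "benjamini_hochberg",
    "fisher_exact_2x2",
    "fisher_exact_many",
    "jonckheere_terpstra",
]

# Relative tolerance used to treat hypergeometric probabilities as tied
# with the observed table when accumulating the two-sided p-value.
TIE_EPS = 1e-7


def _fisher_group(r1: int, r2: int, c1: int, a_values: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p for tables sharing margins (r1, r2, c1).

    All tables with row sums ``r1``, ``r2`` and first-column sum ``c1``
    share one hypergeometric support; ``a_values`` are the observed
    top-left cells.  The two-sided p-value sums the probabilities of all
    tables no more probable than the observed one (ties within a
    relative tolerance of ``TIE_EPS`` are included).
    """
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    # index of the last sorted pmf <= pmf_obs * (1 + eps), for each observation
    thresholds = pmf[a_values - lo] * (1.0 + TIE_EPS)
    idx = np.searchsorted(sorted_pmf, thresholds, side="right")
    return np.minimum(cum[idx - 1], 1.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test p-value for the 2x2 table [[a, b], [c, d]].

    Parameters are the four cell counts; rows are the two groups being
    compared (e.g. tumor vs normal), columns alt vs ref reads.

    Raises
    ------
    ValueError
        If any cell is negative or either row sum is zero (the
        conditional test is undefined with an empty margin).
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError(f"cell counts must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if a + b == 0 or c + d == 0:
        raise ValueError("Fisher test undefined: a row sum is zero")
    return float(_fisher_group(a + b, c + d, a + c, np.array([a]))[0])


def fisher_exact_many(tables: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p-values for an (n, 4) array of tables (a, b, c, d).

    Tables are grouped by margins so each distinct hypergeometric
    support is evaluated once; orders of magnitude faster than a scalar
    loop on variant-scale inputs.
    """
    tables = np.asarray(tables)
    if tables.ndim != 2 or tables.shape[1] != 4:
        raise ValueError("expected an (n, 4) array of 2x2 cell counts")
    if np.any(tables < 0):
        raise ValueError("cell counts must be non-negative")
    a, b, c, d = tables.T
    r1, r2, c1 = a + b, c + d, a + c
    if np.any(r1 == 0) or np.any(r2 == 0):
        raise ValueError("Fisher test undefined: a row sum is zero")
    p = np.empty(len(tables))
    keys = np.stack([r1, r2, c1], axis=1)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    for gi, (g_r1, g_r2, g_c1) in enumerate(uniq):
        mask = inv == gi
        p[mask] = _fisher_group(int(g_r1), int(g_r2), int(g_c1), a[mask])
    return p


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted q-values.

    q(i) = min_{j >= i, sorted order} p(j) * m / j, capped at 1, returned
    in the original input order.  Output is monotone in p and invariant
    to permutations of the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """Jonckheere-Terpstra J: summed Mann-Whitney counts over ordered pairs."""
    j = 0.0
    for x, y in itertools.combinations(groups, 2):
        diff = y[None, :] - x[:, None]
        j += np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return j


def jonckheere_terpstra(
    groups: Sequence[np.ndarray],
    exact_limit: int = 200_000,
) -> tuple[float, float, float]:
    """Jonckheere-Terpstra test for an ordered alternative across k groups.

    ``groups`` must be given in the hypothesized increasing order.  The
    statistic is the sum over all ordered group pairs of Mann-Whitney
    counts (ties counted 0.5).  The two-sided p-value is computed by
    exact permutation when the number of distinct group assignments is
    at most ``exact_limit`` (covers every total n <= 12 and most larger
    unbalanced layouts), otherwise by the standard normal approximation
    with the no-ties null variance.

    Returns
    -------
    (J, z, p) : statistic, standardized statistic, two-sided p-value.
    """
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2 or any(len(g) < 1 for g in arrs):
        raise ValueError("need at least two non-empty groups")
    sizes = [len(g) for g in arrs]
    n = sum(sizes)
    mean = (n**2 - sum(s**2 for s in sizes)) / 4.0
    var = (n**2 * (2 * n + 3) - sum(s**2 * (2 * s + 3) for s in sizes)) / 72.0
    j = _jt_statistic(arrs)
    z = 0.0 if var == 0 else (j - mean) / math.sqrt(var)

    n_arrangements = math.factorial(n)
    for s in sizes:
        n_arrangements //= math.factorial(s)
    if n_arrangements <= exact_limit:
        pooled = np.concatenate(arrs)
        obs_dev = abs(j - mean)
        hits = 0
        total = 0
        for assign in _multiset_assignments(n, sizes):
            perm_groups = [pooled[idx] for idx in assign]
            jj = _jt_statistic(perm_groups)
            # small slack so float-identical deviations count as ties
            if abs(jj - mean) >= obs_dev - 1e-9:
                hits += 1
            total += 1
        return j, z, hits / total
    p = 2.0 * sps.norm.sf(abs(z))
    return j, z, min(p, 1.0)


def _multiset_assignments(n: int, sizes: list[int]):
    """Yield all partitions of indices 0..n-1 into ordered groups of given sizes."""

    def rec(remaining: tuple[int, ...], k: int):
        if k == len(sizes) - 1:
            yield [np.array(remaining, dtype=int)]
            return
        for chosen in itertools.combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in set(chosen))
            for tail in rec(rest, k + 1):
                yield [np.array(chosen, dtype=int)] + tail

    yield from rec(tuple(range(n)), 0)
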