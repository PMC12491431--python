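"""Overlap statistics for target-gene sets.

Hypergeometric upper-tail enrichment, two-sided Fisher's exact test (by
summing all tables with fixed margins whose point probability does not
exceed the observed one), and Benjamini-Hochberg step-up adjustment.  The
background universe N is always an explicit argument: enrichment p-values
are meaningless without a stated universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapTest",
    "hypergeom_enrichment",
    "fisher_exact_2x2",
    "bh_adjust",
    "overlap_test",
]


@dataclass(frozen=True)
class OverlapTest:
    """Overlap of a gene set of size n with a pathway of size K drawn from a
    background of N genes, with k genes shared."""

    k: int
    n: int
    K: int
    N: int
    pvalue: float
    fold_enrichment: float


def _check_overlap(k, n, K, N) -> None:
    if min(k, n, K, N) < 0 or max(n, K) > N:
        raise ValueError(f"invalid overlap configuration k={k} n={n} K={K} N={N}")
    if k > min(n, K):
        raise ValueError(f"overlap k={k} exceeds min(n={n}, K={K})")


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for drawing n genes from
    a background of N containing K pathway genes."""
    _check_overlap(k, n, K, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Sums the probabilities of every table with the observed margins whose
    point probability is no larger than the observed table's (the usual
    two-sided convention).  A zero margin makes the table degenerate; the
    test returns 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table must be 2x2 with non-negative integer cells")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_test(set_a: set[str], set_b: set[str], background: set[str]) -> OverlapTest:
    """Hypergeometric enrichment of two gene sets against an explicit
    background universe (genes outside the universe are dropped first)."""
    a = set_a & background
    b = set_b & background
    k, n, K, N = len(a & b), len(a), len(b), len(background)
    _check_overlap(k, n, K, N)
    p = hypergeom_enrichment(k, n, K, N)
    fold = (k / n) / (K / N) if n and K else float("nan")
    return OverlapTest(k, n, K, N, p, fold)
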