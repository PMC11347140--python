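"""Count-table statistics: G-test, replicate homogeneity, BH FDR.

The G-test (likelihood-ratio test of independence/homogeneity) is the
workhorse for differential trans-splicing: G = 2 * sum O * ln(O / E) with
expectations from the row/column marginals, compared against the chi-square
upper tail with (r-1)(c-1) degrees of freedom.  Zero observed cells
contribute 0 to the sum.
"""

from __future__ import annotations

import math
from typing import Sequence, Tuple

import numpy as np
from scipy.stats import chi2

__all__ = ["g_test", "homogeneity_test", "bh_fdr", "pearson_chi2"]


def _clean_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("g_test requires a 2-D count table")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    # drop all-zero rows/columns; they carry no information
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0] if arr.size else arr
    return arr


def g_test(table) -> Tuple[float, int, float]:
    """Likelihood-ratio (G) test of independence on an r x c count table.

    Returns ``(G, df, p)``.  Degenerate tables (fewer than 2 informative rows
    or columns after dropping empty ones) return ``(0.0, 0, 1.0)``.
    """
    arr = _clean_table(table)
    if arr.size == 0 or arr.shape[0] < 2 or arr.shape[1] < 2:
        return 0.0, 0, 1.0
    total = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total
    obs = arr[arr > 0]
    exp = expected[arr > 0]
    g = 2.0 * float(np.sum(obs * np.log(obs / exp)))
    g = max(g, 0.0)  # guard tiny negative rounding on homogeneous tables
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    p = float(chi2.sf(g, df))
    return g, df, p


def pearson_chi2(table) -> float:
    """Pearson chi-square statistic (no continuity correction).

    Used for decile threshold selection; degenerate tables score 0.
    """
    arr = _clean_table(table)
    if arr.size == 0 or arr.shape[0] < 2 or arr.shape[1] < 2:
        return 0.0
    total = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total
    return float(np.sum((arr - expected) ** 2 / expected))


def homogeneity_test(replicate_counts: Sequence[Sequence[float]]) -> float:
    """G-test of homogeneity across replicates of one genotype.

    `replicate_counts` is a sequence of ``(n_trans_spliced, n_retained)``
    pairs, one per replicate.  Replicates with zero reads are dropped.  With
    fewer than two informative replicates the test is undefined and the site
    passes by default (returns NaN; callers treat NaN as a pass).
    """
    rows = [r for r in replicate_counts if sum(r) > 0]
    if len(rows) < 2:
        return float("nan")
    _, _, p = g_test(rows)
    return p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    Output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = ranked
    return out
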