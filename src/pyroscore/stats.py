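"""Shared statistical primitives.

Two primitives live here rather than behind a library call:

* A vectorised exact one-sample Wilcoxon signed-rank test. Proteomic change
  tables test thousands of proteins on the same handful of patient pairs, so
  the exact null distribution of the W+ statistic is built once per row-length
  and reused across all proteins.
* The Yates-corrected Pearson chi-square for a 2x2 table. The correction is
  clamped (``min(0.5, |O - E|)``) so that tables whose observed counts sit
  within half a unit of expectation yield a statistic of exactly zero, the
  textbook convention.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "signed_rank_exact_pvalues",
    "yates_chi2_2x2",
]


@lru_cache(maxsize=64)
def _wplus_cdf(n: int) -> np.ndarray:
    """CDF of the W+ signed-rank statistic under H0 for ``n`` untied pairs.

    Built by the standard generating-function recursion: each rank r in 1..n
    contributes either 0 or r to W+ with probability 1/2.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: total + 1 - r].copy()
    return np.cumsum(counts) / 2.0**n


def _exact_p_tied(ranks: np.ndarray, wplus: float) -> float:
    """Exact two-sided p for one row with tied (average) ranks.

    The rank vector is fixed by |d|; under H0 each rank enters W+
    independently with probability 1/2, so the same generating-function DP
    applies. Average ranks are multiples of 1/2, so doubling makes the DP
    integer-valued. This is the exact test conditional on the observed ties.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total2 = int(r2.sum())
    counts = np.zeros(total2 + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total2 + 1 - r].copy()
    cdf = np.cumsum(counts) / 2.0 ** len(r2)
    w2 = int(np.rint(2 * wplus))
    wmin2 = min(w2, total2 - w2)
    return float(min(1.0, 2.0 * cdf[wmin2]))


_EXACT_MAX_N = 25


def signed_rank_exact_pvalues(diffs: np.ndarray) -> np.ndarray:
    """Two-sided exact one-sample Wilcoxon signed-rank p-values, row-wise.

    Parameters
    ----------
    diffs
        Array of shape ``(m, n)``: m variables, n paired differences each.

    Zeros are dropped (Wilcoxon's original treatment); tied absolute
    differences are handled exactly through average ranks (the sign-flip
    enumeration conditions on the observed rank vector). Rows whose reduced
    length exceeds 25 use the tie-corrected normal approximation via
    :func:`scipy.stats.wilcoxon`; rows that are entirely zero get p = 1 (no
    evidence of change in either direction).

    Returns
    -------
    ndarray of shape ``(m,)`` of two-sided p-values.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim == 1:
        diffs = diffs[None, :]
    m, n = diffs.shape
    if n < 1:
        raise ValueError("need at least one paired difference")

    pvals = np.empty(m, dtype=float)

    absd = np.abs(diffs)
    has_zero = (absd == 0).any(axis=1)
    sorted_abs = np.sort(absd, axis=1)
    has_tie = (np.diff(sorted_abs, axis=1) == 0).any(axis=1) if n > 1 else np.zeros(m, bool)
    clean = ~(has_zero | has_tie)

    if n <= _EXACT_MAX_N and clean.any():
        # fast path: untied rows share one cached null distribution
        ranks = sps.rankdata(absd[clean], axis=1)
        wplus = np.rint((ranks * (diffs[clean] > 0)).sum(axis=1)).astype(int)
        total = n * (n + 1) // 2
        cdf = _wplus_cdf(n)
        # symmetric null: two-sided p = 2 * P(W+ <= min(w, total - w))
        wmin = np.minimum(wplus, total - wplus)
        pvals[clean] = np.minimum(1.0, 2.0 * cdf[wmin])
        rest = np.flatnonzero(~clean)
    else:
        rest = np.arange(m)

    for i in rest:
        d = diffs[i]
        nz = d[d != 0]
        if nz.size == 0:
            pvals[i] = 1.0
            continue
        if nz.size <= _EXACT_MAX_N:
            ranks = sps.rankdata(np.abs(nz))
            pvals[i] = _exact_p_tied(ranks, float(ranks[nz > 0].sum()))
        else:
            res = sps.wilcoxon(
                nz, zero_method="wilcox", alternative="two-sided", method="approx"
            )
            pvals[i] = res.pvalue
    return pvals


def yates_chi2_2x2(table: np.ndarray) -> tuple[float, float, float, float]:
    """Pearson chi-square on a 2x2 table, with and without Yates correction.

    Returns ``(chi2_yates, p_yates, chi2_uncorrected, p_uncorrected)``.
    A zero row margin (an empty group) raises ``ValueError``; a zero column
    margin means identical proportions and yields statistic 0, p = 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("cell counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any():
        raise ValueError("degenerate 2x2 table: a group margin is zero")
    if (cols == 0).any():
        return 0.0, 1.0, 0.0, 1.0
    expected = np.outer(rows, cols) / obs.sum()
    dev = np.abs(obs - expected)
    chi2_raw = float((dev**2 / expected).sum())
    dev_corr = np.maximum(dev - 0.5, 0.0)
    chi2_yates = float((dev_corr**2 / expected).sum())
    p_yates = float(sps.chi2.sf(chi2_yates, df=1))
    p_raw = float(sps.chi2.sf(chi2_raw, df=1))
    return chi2_yates, p_yates, chi2_raw, p_raw
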