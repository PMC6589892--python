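"""Statistical primitives: paired Wilcoxon signed-rank test, FDR, genomic inflation.

The paired WSR test is the workhorse of the whole analysis: per testing unit it
compares the paternal and maternal read counts across individuals under
H0: the paternal-maternal differences are symmetric about zero.  For small
numbers of informative pairs the p value is computed from the *exact*
sign-permutation distribution of the signed-rank statistic (ties handled with
midranks); for larger n the usual normal approximation with tie correction is
used.  Zero differences are discarded before ranking (classic Wilcoxon
handling), which is configurable.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wsr_paired_test",
    "bh_fdr",
    "genomic_inflation",
]

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(sps.chi2.isf(0.5, 1))


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Return (2*W+, integer 2*midranks, n) for nonzero differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, np.zeros(0, dtype=np.int64), 0
    ranks = sps.rankdata(np.abs(d))  # midranks; .5 steps at ties
    ranks2 = np.rint(2.0 * ranks).astype(np.int64)
    w2 = float(ranks2[d > 0].sum())
    return w2, ranks2, n


def _exact_sign_perm_p(w2: float, ranks2: np.ndarray) -> float:
    """Two-sided exact p over all 2^n equiprobable sign assignments.

    Dynamic programming over the achievable values of 2*W+ (integer because
    midranks are half-integers).  p = min(1, 2*min(P(W+ <= w), P(W+ >= w))).
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        nxt = 0.5 * dist
        nxt[r:] += 0.5 * dist[: total + 1 - r]
        dist = nxt
    w = int(round(w2))
    p_le = float(dist[: w + 1].sum())
    p_ge = float(dist[w:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_approx_p(w2: float, ranks2: np.ndarray, n: int) -> float:
    """Normal approximation with tie correction (no continuity correction)."""
    mean2 = n * (n + 1) / 2.0  # 2 * n(n+1)/4
    # var of W+ with ties: n(n+1)(2n+1)/24 - sum(t^3 - t)/48 ; on the 2x scale x4
    _, counts = np.unique(ranks2, return_counts=True)
    tie_term = float(((counts**3 - counts) * 1.0).sum())
    var2 = 4.0 * (n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0)
    if var2 <= 0:
        return 1.0
    z = (w2 - mean2) / np.sqrt(var2)
    return float(2.0 * sps.norm.sf(abs(z)))


def wsr_paired_test(
    pat_counts,
    mat_counts,
    *,
    exact_threshold: int = 25,
    zero_method: str = "discard",
    method: str = "auto",
) -> float:
    """Two-sided paired Wilcoxon signed-rank p value for pat vs mat counts.

    Parameters
    ----------
    pat_counts, mat_counts
        Equal-length vectors of aggregated paternal / maternal read counts,
        one entry per informative individual.
    exact_threshold
        Use the exact sign-permutation distribution when the number of
        nonzero differences is <= this value; normal approximation otherwise.
    zero_method
        Only ``"discard"`` (drop zero differences before ranking) is
        implemented; the parameter exists so the choice is explicit.
    method
        ``"auto"`` (default), ``"exact"`` or ``"approx"``.
    """
    if zero_method != "discard":
        raise NotImplementedError("only zero_method='discard' is supported")
    pat = np.asarray(pat_counts, dtype=float)
    mat = np.asarray(mat_counts, dtype=float)
    if pat.shape != mat.shape:
        raise ValueError("pat_counts and mat_counts must have equal length")
    w2, ranks2, n = _signed_rank_statistic(pat - mat)
    if n == 0:
        return 1.0
    if method == "exact" or (method == "auto" and n <= exact_threshold):
        return _exact_sign_perm_p(w2, ranks2)
    return _normal_approx_p(w2, ranks2, n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor lambda.

    Median of the chi-square(1) quantile transform of 1-p, divided by the
    chi-square(1) median (~0.4549).  Calibrated tests give lambda ~= 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p values to estimate inflation")
    p = np.clip(p, 1e-300, 1.0)
    stat = sps.chi2.isf(p, 1)
    return float(np.median(stat) / CHI2_1_MEDIAN)
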