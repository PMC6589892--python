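"""Chromosome X: inactivation-ratio estimation, skew filtering, weighted test.

Random X inactivation makes a female's chrX allelic ratio reflect which X is
active in her blood/cell-line clone mix, not imprinting.  The X-chromosome
inactivation ratio (XCIR) is the pooled paternal read fraction over all
informative X-linked genes:

    XCIR = sum_i patCount_i / (sum_i patCount_i + sum_i matCount_i)

Females with skewed inactivation (XCIR < 0.2 or > 0.8, strict) are
excluded; in the rest, per-gene paternal/maternal counts are reweighted so
that a non-imprinted gene is expected at ratio 0.5, and the paired WSR test
is run as on the autosomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_fdr, wsr_paired_test

__all__ = ["estimate_xcir", "filter_skewed", "adjust_counts", "xcir_weighted_test"]


def estimate_xcir(
    pat: np.ndarray, mat: np.ndarray, sample_ids=None, lo: float = 0.2, hi: float = 0.8
) -> pd.DataFrame:
    """Per-female XCIR from an X-gene (genes x females) count matrix.

    Females with zero total X counts get no record (they are excluded with
    reason ``no_counts`` in the companion list returned via the attrs dict).
    Columns: sample, xcir, skewed, m (number of X genes with counts).
    """
    pat = np.asarray(pat)
    mat = np.asarray(mat)
    n = pat.shape[1]
    if sample_ids is None:
        sample_ids = [f"F{i:03d}" for i in range(n)]
    tot_p = pat.sum(axis=0).astype(float)
    tot_m = mat.sum(axis=0).astype(float)
    total = tot_p + tot_m
    has = total > 0
    m_genes = ((pat + mat) > 0).sum(axis=0)
    xcir = np.where(has, tot_p / np.maximum(total, 1), np.nan)
    rec = pd.DataFrame(
        {
            "sample": np.asarray(sample_ids)[has],
            "xcir": xcir[has],
            "skewed": (xcir[has] < lo) | (xcir[has] > hi),
            "m": m_genes[has],
        }
    )
    rec.attrs["excluded_no_counts"] = list(np.asarray(sample_ids)[~has])
    return rec


def filter_skewed(records: pd.DataFrame, lo: float = 0.2, hi: float = 0.8) -> pd.DataFrame:
    """Retain females with lo <= XCIR <= hi (strict exclusion; boundaries kept)."""
    keep = ~((records["xcir"] < lo) | (records["xcir"] > hi))
    return records[keep].reset_index(drop=True)


def adjust_counts(
    pat: np.ndarray, mat: np.ndarray, xcir: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale counts so XCIR-driven skew is removed, preserving pair totals.

    Paternal counts are weighted by 0.5/xcir and maternal by 0.5/(1-xcir),
    then renormalized to the original pat+mat total and rounded half-even,
    with the maternal count taking the remainder (totals preserved exactly).
    """
    xcir = np.asarray(xcir, dtype=float)
    if np.any((xcir <= 0) | (xcir >= 1)):
        raise AssertionError("retained samples must have XCIR strictly inside (0, 1)")
    pat = np.asarray(pat, dtype=float)
    mat = np.asarray(mat, dtype=float)
    wp = 0.5 / xcir[None, :]
    wm = 0.5 / (1.0 - xcir[None, :])
    sp, sm = pat * wp, mat * wm
    tot = pat + mat
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(sp + sm > 0, sp / np.maximum(sp + sm, 1e-300), 0.0)
    pat_adj = np.rint(tot * frac).astype(np.int64)
    mat_adj = tot.astype(np.int64) - pat_adj
    return pat_adj, mat_adj


def xcir_weighted_test(
    pat: np.ndarray,
    mat: np.ndarray,
    records: pd.DataFrame,
    sample_ids=None,
    fdr: float = 0.1,
    min_informative_fraction: float = 0.10,
) -> pd.DataFrame:
    """Paired WSR on XCIR-adjusted counts per X gene (non-skewed females only).

    ``pat``/``mat`` are genes x females matrices aligned with ``sample_ids``
    (default F000..); ``records`` is the (already skew-filtered) XCIR table.
    """
    pat = np.asarray(pat)
    mat = np.asarray(mat)
    n = pat.shape[1]
    if sample_ids is None:
        sample_ids = [f"F{i:03d}" for i in range(n)]
    sample_ids = list(sample_ids)
    keep_idx = [sample_ids.index(s) for s in records["sample"]]
    pat_k = pat[:, keep_idx]
    mat_k = mat[:, keep_idx]
    pat_adj, mat_adj = adjust_counts(pat_k, mat_k, records["xcir"].values)

    n_kept = len(keep_idx)
    rows = []
    for gi in range(pat.shape[0]):
        inf = (pat_adj[gi] + mat_adj[gi]) >= 1
        n_inf = int(inf.sum())
        tested = n_inf >= min_informative_fraction * n_kept and n_inf > 0
        p = wsr_paired_test(pat_adj[gi][inf], mat_adj[gi][inf]) if tested else np.nan
        tot = pat_adj[gi][inf] + mat_adj[gi][inf]
        ratio = float(np.mean(pat_adj[gi][inf] / tot)) if n_inf else np.nan
        rows.append(
            {
                "gene_index": gi,
                "n_informative": n_inf,
                "mean_pat_ratio": ratio,
                "p_wsr": p,
            }
        )
    out = pd.DataFrame(rows)
    tested_mask = out["p_wsr"].notna()
    out["q_wsr"] = np.nan
    if tested_mask.any():
        out.loc[tested_mask, "q_wsr"] = bh_fdr(out.loc[tested_mask, "p_wsr"].values)
    out["significant"] = out["q_wsr"] < fdr
    return out
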