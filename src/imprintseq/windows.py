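"""Annotation-free genome scan for parent-of-origin expression bias.

Sliding 25-kb windows (5-kb step) pool oriented paternal/maternal counts
over all heterozygous SNVs they contain and run the paired WSR test per
window, which finds imprinted transcription outside known gene models.  A
companion permutation test asks whether windows near strongly imprinted
genes (paternal ratio <= 0.1 or >= 0.9) are enriched for bias signals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_fdr, wsr_paired_test

__all__ = ["tile_windows", "scan", "enrichment_near_strong_genes"]


def tile_windows(
    chrom_sizes: dict[str, int], width: int = 25_000, step: int = 5_000, offset: int = 0
) -> pd.DataFrame:
    """Full windows anchored at ``offset``: starts offset, offset+step, ...

    No partial windows: start + width must not exceed the chromosome length.
    """
    if not (width >= step > 0):
        raise ValueError("require width >= step > 0")
    rows = []
    for ch, size in chrom_sizes.items():
        starts = np.arange(offset, size - width + 1, step, dtype=np.int64)
        for s in starts:
            rows.append({"chrom": ch, "start": int(s), "end": int(s + width)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def scan(
    site_counts: pd.DataFrame,
    chrom_sizes: dict[str, int],
    width: int = 25_000,
    step: int = 5_000,
    min_informative_fraction: float = 0.10,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """WSR scan over sliding windows; returns per-window counts, p and q.

    ``site_counts`` carries oriented counts (chrom, pos 1-based, sample,
    pat_count, mat_count); rows with missing parental orientation are
    ignored.  Windows with no informative SNV are skipped (not scored);
    windows informative in fewer than ``min_informative_fraction`` of
    samples are reported but not tested.
    """
    if width % step != 0:
        raise ValueError("width must be a multiple of step for the sliding grid")
    df = site_counts.dropna(subset=["pat_count", "mat_count"]).copy()
    samples = sorted(df["sample"].unique()) if n_samples is None else None
    k = width // step
    parts = []
    for j in range(k):
        d = df.copy()
        d["widx"] = (d["pos"] - 1) // step - j
        parts.append(d)
    expanded = pd.concat(parts, ignore_index=True)
    expanded = expanded[expanded["widx"] >= 0]
    expanded["wstart"] = expanded["widx"] * step
    sizes = expanded["chrom"].map(chrom_sizes)
    expanded = expanded[expanded["wstart"] + width <= sizes]

    grouped = expanded.groupby(["chrom", "wstart", "sample"], sort=True)[
        ["pat_count", "mat_count"]
    ].sum()
    rows = []
    n_total = len(samples) if n_samples is None else n_samples
    for (ch, ws), sub in grouped.groupby(level=[0, 1], sort=True):
        pat = sub["pat_count"].values
        mat = sub["mat_count"].values
        inf = (pat + mat) >= 1
        n_inf = int(inf.sum())
        if n_inf == 0:
            continue
        tested = n_inf >= min_informative_fraction * n_total
        p = wsr_paired_test(pat[inf], mat[inf]) if tested else np.nan
        rows.append(
            {
                "chrom": ch,
                "start": int(ws),
                "end": int(ws + width),
                "n_informative": n_inf,
                "pat_sum": int(pat.sum()),
                "mat_sum": int(mat.sum()),
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_informative", "pat_sum", "mat_sum", "p"]
    )
    out["q"] = np.nan
    tested_mask = out["p"].notna()
    if tested_mask.any():
        out.loc[tested_mask, "q"] = bh_fdr(out.loc[tested_mask, "p"].values)
    return out


def enrichment_near_strong_genes(
    windows: pd.DataFrame,
    strong_genes: pd.DataFrame,
    flank: int = 250_000,
    n_perm: int = 1999,
    seed: int = 0,
) -> dict:
    """Permutation p for enrichment of bias signal near strongly imprinted genes.

    ``windows``: non-overlapping scored bins (chrom, start, end, p);
    ``strong_genes``: intervals of genes with paternal ratio <= 0.1 or
    >= 0.9 (chrom, start, end).  A bin is "near" if it lies within ``flank``
    of a strong gene and does not overlap a *different* strong gene.  The
    observed statistic is mean(-log10 p) over near bins; the null draws
    equally many bins uniformly (without replacement) from all scored bins;
    p = (r + 1) / (n_perm + 1).
    """
    w = windows.dropna(subset=["p"]).reset_index(drop=True)
    if strong_genes.empty:
        raise ValueError("strong_genes must be non-empty")
    ws, we = w["start"].values, w["end"].values
    same = {}
    overlap = np.zeros((len(strong_genes), len(w)), dtype=bool)
    within = np.zeros_like(overlap)
    for gi, (_, g) in enumerate(strong_genes.iterrows()):
        on_chrom = (w["chrom"] == g["chrom"]).values
        overlap[gi] = on_chrom & (ws < g["end"]) & (we > g["start"])
        within[gi] = on_chrom & (ws < g["end"] + flank) & (we > g["start"] - flank)
    # a bin enters via gene A if it lies within the flank of A and overlaps
    # no strong gene other than A itself
    any_other_overlap = overlap.sum(axis=0)[None, :] - overlap.astype(int)
    near = (within & (any_other_overlap == 0)).any(axis=0)

    n_near = int(near.sum())
    if n_near == 0:
        raise ValueError("no informative bins near strong genes")
    if len(w) < n_near:
        raise ValueError("fewer informative bins than the near-gene set size")
    neglog = -np.log10(np.clip(w["p"].values, 1e-300, 1.0))
    observed = float(neglog[near].mean())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        draw = rng.choice(len(w), size=n_near, replace=False)
        if neglog[draw].mean() >= observed:
            exceed += 1
    return {
        "p": (exceed + 1) / (n_perm + 1),
        "observed": observed,
        "n_near": n_near,
        "n_total": len(w),
        "n_perm": n_perm,
    }
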