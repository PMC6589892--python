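"""Site filtering, parental orientation of allelic counts, UGF aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "filter_sites",
    "orient_counts",
    "aggregate_by_unit",
    "ParentalCountMatrix",
]


def filter_sites(
    snvs: pd.DataFrame,
    masks: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNVs falling in any exclusion mask; log which mask(s) hit each site.

    ``snvs`` has columns chrom, pos (1-based); each mask is a BED-like frame
    with chrom, start, end (0-based half-open) — typically low-mappability
    regions, common CNVs, segmental duplications and simple repeats.
    Returns (retained snvs, removal log with columns chrom, pos, masks).
    """
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], IntervalTree] = {}
    for name, bed in masks.items():
        for ch, sub in bed.groupby("chrom", sort=False):
            tree = IntervalTree()
            for s, e in zip(sub["start"].values, sub["end"].values):
                if e > s:
                    tree[s:e] = True
            trees[(name, ch)] = tree
    sites = snvs[["chrom", "pos"]].drop_duplicates()
    hit_lists: dict[tuple[str, int], list[str]] = {}
    for ch, sub in sites.groupby("chrom", sort=False):
        for name in masks:
            tree = trees.get((name, ch))
            if tree is None:
                continue
            for pos in sub["pos"].values:
                if tree.overlaps_point(int(pos) - 1):
                    hit_lists.setdefault((ch, int(pos)), []).append(name)
    if hit_lists:
        removed = pd.DataFrame(
            [
                {"chrom": ch, "pos": pos, "masks": ",".join(names)}
                for (ch, pos), names in sorted(hit_lists.items())
            ]
        )
        key = snvs["chrom"].astype(str) + ":" + snvs["pos"].astype(str)
        bad = key.isin(removed["chrom"].astype(str) + ":" + removed["pos"].astype(str))
        retained = snvs[~bad].reset_index(drop=True)
    else:
        removed = pd.DataFrame(columns=["chrom", "pos", "masks"])
        retained = snvs.reset_index(drop=True)
    return retained, removed


def orient_counts(site_counts: pd.DataFrame, pofo_calls: pd.DataFrame) -> pd.DataFrame:
    """Turn ref/alt counts into paternal/maternal counts using PofO calls.

    Sites x samples with missing PofO keep their ref/alt counts (useful for
    the reference-bias tally) but get pat/mat = NA; sites whose PofO alleles
    are inconsistent with the observed ref/alt alleles are flagged
    (``inconsistent``) and likewise excluded from parental counts.
    """
    if "ref_base" not in site_counts.columns:
        raise ValueError("site_counts must carry a 'ref_base' column to orient counts")
    merged = site_counts.merge(
        pofo_calls, on=["chrom", "pos", "sample"], how="left", validate="many_to_one"
    )
    merged["status"] = merged["status"].fillna("missing")
    known = merged["status"].isin(["window_match", "mendelian"])
    pat_is_ref = merged["paternal_allele"] == merged["ref_base"]
    consistent = known & (pat_is_ref | (merged["maternal_allele"] == merged["ref_base"]))
    merged["inconsistent"] = known & ~consistent
    assigned = consistent
    pat = np.where(pat_is_ref, merged["ref_count"], merged["alt_count"])
    mat = np.where(pat_is_ref, merged["alt_count"], merged["ref_count"])
    merged["pat_count"] = np.where(assigned, pat, np.nan)
    merged["mat_count"] = np.where(assigned, mat, np.nan)
    return merged


@dataclass
class ParentalCountMatrix:
    """Aggregated paternal/maternal (and ref/alt) counts per unit x sample."""

    unit_ids: np.ndarray
    sample_ids: np.ndarray
    pat: np.ndarray  # (U, S) int
    mat: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.pat, self.mat, self.ref, self.alt):
            if a.shape != (len(self.unit_ids), len(self.sample_ids)):
                raise ValueError("count matrices must be units x samples")

    @property
    def n_informative(self) -> np.ndarray:
        return ((self.pat + self.mat) >= 1).sum(axis=1)

    def pat_ratio(self) -> np.ndarray:
        """Mean per-sample paternal ratio over informative samples, per unit."""
        tot = self.pat + self.mat
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(tot > 0, self.pat / np.maximum(tot, 1), np.nan)
        return np.nanmean(np.where(tot > 0, r, np.nan), axis=1)


def aggregate_by_unit(
    oriented: pd.DataFrame,
    unit_ids: pd.Series,
    sample_ids: list,
    min_informative_fraction: float = 0.10,
) -> tuple[ParentalCountMatrix, pd.DataFrame]:
    """Sum oriented site counts to unit level and apply the informativeness rule.

    ``oriented`` is the output of :func:`orient_counts`; ``unit_ids`` aligns
    with its rows (UGF or window id per site; NA rows are unassigned and
    skipped).  Units informative (pat+mat >= 1) in at least
    ``min_informative_fraction`` of samples are marked ``tested`` in the
    returned summary; the matrix keeps all units so the reference-bias tally
    (which also uses missing-PofO sites) stays complete.
    """
    df = oriented.copy()
    df["unit_id"] = unit_ids.values
    df = df[df["unit_id"].notna()]
    units = np.array(sorted(df["unit_id"].unique()))
    s_index = {s: i for i, s in enumerate(sample_ids)}
    u_index = {u: i for i, u in enumerate(units)}
    shape = (len(units), len(sample_ids))
    pat = np.zeros(shape, dtype=np.int64)
    mat = np.zeros(shape, dtype=np.int64)
    ref = np.zeros(shape, dtype=np.int64)
    alt = np.zeros(shape, dtype=np.int64)
    ui = df["unit_id"].map(u_index).values.astype(int)
    si = df["sample"].map(s_index).values.astype(int)
    has_pofo = df["pat_count"].notna().values
    np.add.at(pat, (ui[has_pofo], si[has_pofo]), df["pat_count"].values[has_pofo].astype(np.int64))
    np.add.at(mat, (ui[has_pofo], si[has_pofo]), df["mat_count"].values[has_pofo].astype(np.int64))
    np.add.at(ref, (ui, si), df["ref_count"].values.astype(np.int64))
    np.add.at(alt, (ui, si), df["alt_count"].values.astype(np.int64))
    pcm = ParentalCountMatrix(
        unit_ids=units, sample_ids=np.asarray(sample_ids), pat=pat, mat=mat, ref=ref, alt=alt
    )
    n_inf = pcm.n_informative
    threshold = min_informative_fraction * len(sample_ids)
    summary = pd.DataFrame(
        {
            "unit_id": units,
            "n_informative": n_inf,
            "tested": n_inf >= threshold,
            "mean_pat_ratio": pcm.pat_ratio(),
        }
    )
    return pcm, summary
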