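"""End-to-end driver: genotypes + allelic counts + gene models -> results.

Stages: parent-of-origin assignment from phased trios, optional exclusion
masks, orientation of ref/alt counts into paternal/maternal, UGF
aggregation, and the two-test imprinting model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import assign_snvs_to_ugfs, build_ugfs
from .counts import aggregate_by_unit, filter_sites, orient_counts
from .model import ImprintingModel, ImprintingResults
from .pofo import assign_parent_of_origin

__all__ = ["analyze_cohort", "oriented_site_counts"]


def oriented_site_counts(
    trios,
    site_counts: pd.DataFrame,
    masks: dict[str, pd.DataFrame] | None = None,
    window_size: int = 100,
    slide: int = 50,
) -> pd.DataFrame:
    """PofO-oriented per-site counts (shared by the UGF and window analyses)."""
    counts = site_counts.copy()
    if "ref_base" not in counts.columns:
        chrom = np.asarray(trios.chrom)
        if chrom.ndim == 0:
            chrom = np.full(np.asarray(trios.positions).size, str(chrom))
        base = pd.DataFrame({"chrom": chrom, "pos": trios.positions, "ref_base": trios.ref})
        counts = counts.merge(base, on=["chrom", "pos"], how="left")
    if masks:
        retained_sites, _ = filter_sites(counts[["chrom", "pos"]].drop_duplicates(), masks)
        key = counts["chrom"].astype(str) + ":" + counts["pos"].astype(str)
        ok = key.isin(retained_sites["chrom"].astype(str) + ":" + retained_sites["pos"].astype(str))
        counts = counts[ok]
    pofo = assign_parent_of_origin(trios, window_size=window_size, slide=slide)
    return orient_counts(counts, pofo)


def analyze_cohort(
    trios,
    site_counts: pd.DataFrame,
    gene_models: pd.DataFrame,
    masks: dict[str, pd.DataFrame] | None = None,
    min_informative_fraction: float = 0.10,
    fdr: float = 0.1,
    sample_ids: list | None = None,
) -> ImprintingResults:
    """Run the full gene-centric analysis and fit the imprinting model.

    ``trios`` provides phased genotypes (see
    :func:`imprintseq.pofo.assign_parent_of_origin`); ``site_counts`` has
    chrom, pos, sample, ref_count, alt_count; ``gene_models`` has chrom,
    start, end, strand, gene_id (0-based half-open).
    """
    oriented = oriented_site_counts(trios, site_counts, masks)
    ugfs = build_ugfs(gene_models)
    unit_ids = assign_snvs_to_ugfs(oriented[["chrom", "pos"]], ugfs)
    if sample_ids is None:
        sample_ids = sorted(site_counts["sample"].unique())
    pcm, _ = aggregate_by_unit(
        oriented, unit_ids, sample_ids, min_informative_fraction=min_informative_fraction
    )
    res = ImprintingModel(pcm, min_informative_fraction=min_informative_fraction).fit(fdr=fdr)
    res.ugfs = ugfs
    return res
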