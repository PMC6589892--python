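"""Unique gene fragments: the interval partition induced by overlapping genes.

A unique gene fragment (UGF) is a maximal genomic interval covered by a
constant set of genes.  Overlapping transcripts are thereby split into
separately testable units, which disambiguates loci such as antisense gene
pairs where the two overlapping transcripts carry opposite parental bias.
Gene bodies span min start to max end over a gene's records, since exonic
and intronic SNVs are aggregated alike.

Coordinates are 0-based half-open internally; GTF (1-based closed) is
converted at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_ugfs", "assign_snvs_to_ugfs", "read_gtf_genes"]


def build_ugfs(gene_models: pd.DataFrame) -> pd.DataFrame:
    """Partition gene bodies into maximal constant-gene-set fragments.

    ``gene_models`` needs columns chrom, start, end (0-based half-open),
    gene_id and optionally strand.  Returns chrom, start, end, ugf_id,
    gene_ids (comma-joined, sorted), strands, n_genes; fragments on a
    chromosome are non-overlapping, their union equals the union of gene
    bodies, and adjacent fragments differ in gene set.
    """
    genes = gene_models.reset_index(drop=True)
    bad = genes[genes["start"] >= genes["end"]]
    if len(bad):
        raise ValueError(f"malformed interval for gene {bad.iloc[0]['gene_id']!r}")
    if "strand" not in genes.columns:
        genes = genes.assign(strand=".")
    # collapse multi-record genes to their body span
    body = (
        genes.groupby(["chrom", "gene_id"], sort=False)
        .agg(start=("start", "min"), end=("end", "max"), strand=("strand", "first"))
        .reset_index()
    )
    rows = []
    for ch, sub in body.groupby("chrom", sort=True):
        bounds = np.unique(np.concatenate([sub["start"].values, sub["end"].values]))
        gstart, gend = sub["start"].values, sub["end"].values
        ids = sub["gene_id"].values
        strands = sub["strand"].values
        prev_key = None
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            cover = (gstart <= lo) & (gend >= hi)
            if not cover.any():
                prev_key = None
                continue
            key = tuple(sorted(ids[cover]))
            if key == prev_key:
                rows[-1]["end"] = int(hi)  # merge maximal runs (shouldn't occur, kept for safety)
            else:
                rows.append(
                    {
                        "chrom": ch,
                        "start": int(lo),
                        "end": int(hi),
                        "gene_ids": ",".join(key),
                        "strands": ",".join(sorted(set(strands[cover]))),
                        "n_genes": int(cover.sum()),
                    }
                )
            prev_key = key
    ugfs = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_ids", "strands", "n_genes"])
    ugfs.insert(3, "ugf_id", [f"UGF{i:06d}" for i in range(len(ugfs))])
    return ugfs


def assign_snvs_to_ugfs(snv_positions: pd.DataFrame, ugfs: pd.DataFrame) -> pd.Series:
    """Map each SNV (columns chrom, pos; 1-based) to its UGF id or <NA>.

    Fragments are non-overlapping within a chromosome, so a sorted interval
    lookup suffices.  For stranded data, build per-strand UGF sets (filter
    the gene models by strand before :func:`build_ugfs`) and call this once
    per strand.
    """
    out = pd.Series(pd.NA, index=snv_positions.index, dtype="object", name="ugf_id")
    for ch, sub in snv_positions.groupby("chrom", sort=False):
        frag = ugfs[ugfs["chrom"] == ch]
        if frag.empty:
            continue
        starts = frag["start"].values
        ends = frag["end"].values
        ids = frag["ugf_id"].values
        p0 = sub["pos"].values - 1  # to 0-based points
        j = np.searchsorted(starts, p0, side="right") - 1
        hit = (j >= 0) & (p0 < ends[np.clip(j, 0, len(ends) - 1)])
        out.loc[sub.index[hit]] = ids[j[hit]]
    return out


def read_gtf_genes(path) -> pd.DataFrame:
    """Gene bodies from a GTF file (via gffutils), 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "transcript", "exon"):
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        rows.append(
            {
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
                "gene_id": gene_id,
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["chrom", "gene_id"], sort=False)
        .agg(start=("start", "min"), end=("end", "max"), strand=("strand", "first"))
        .reset_index()[["chrom", "start", "end", "strand", "gene_id"]]
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
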