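"""On-disk round trip for simulated cohorts: VCF, TSV counts, GTF, truth, manifest."""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .simulate import Cohort

__all__ = ["write_cohort", "read_counts", "cohort_trio_names"]


def cohort_trio_names(cohort: Cohort) -> list[tuple[str, str, str]]:
    """(mother, father, child) VCF sample-name triples for a simulated cohort."""
    return [
        (f"trio{i:03d}_mother", f"trio{i:03d}_father", f"trio{i:03d}_child")
        for i in range(cohort.trio.n_samples)
    ]


def _write_vcf(cohort: Cohort, path: Path) -> None:
    trio = cohort.trio
    names = cohort_trio_names(cohort)
    cols = [n for triple in names for n in triple]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={trio.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cols) + "\n")
        for v in range(trio.n_snvs):
            gts = []
            for s in range(trio.n_samples):
                for member in (trio.mother, trio.father, trio.child):
                    gts.append(f"{member[s, 0, v]}|{member[s, 1, v]}")
            fh.write(
                f"{trio.chrom}\t{trio.positions[v]}\t.\t{trio.ref[v]}\t{trio.alt[v]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _write_gtf(cohort: Cohort, path: Path) -> None:
    with open(path, "w") as fh:
        for _, g in cohort.genes.iterrows():
            attrs = f'gene_id "{g["gene_id"]}";'
            fh.write(
                f'{g["chrom"]}\timprintseq_sim\tgene\t{g["start"] + 1}\t{g["end"]}\t.'
                f'\t{g["strand"]}\t.\t{attrs}\n'
            )


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write genotypes.vcf, counts.tsv, genes.gtf, truth_genes.tsv, manifest.txt.

    Fails before writing anything if the output directory is not writable;
    the manifest is written last so a complete manifest implies a complete
    cohort.  Fixed config+seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not os.access(outdir, os.W_OK):
        raise PermissionError(f"output directory not writable: {outdir}")
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "counts": outdir / "counts.tsv",
        "gtf": outdir / "genes.gtf",
        "truth": outdir / "truth_genes.tsv",
        "manifest": outdir / "manifest.txt",
    }
    _write_vcf(cohort, paths["vcf"])
    counts = cohort.counts.copy()
    counts["sample"] = counts["sample"].astype(str) + "_child"
    counts.to_csv(paths["counts"], sep="\t", index=False)
    _write_gtf(cohort, paths["gtf"])
    if cohort.truth.genes is not None:
        cohort.truth.genes.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        for k, v in vars(cohort.config).items():
            fh.write(f"{k}: {v}\n")
        fh.write(f"n_snvs: {cohort.trio.n_snvs}\n")
    return paths


def read_counts(path) -> pd.DataFrame:
    """Read a counts.tsv written by :func:`write_cohort`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["sample"] = df["sample"].astype(str)
    return df
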