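"""Parent-of-origin assignment from phased trio genotypes.

Two mechanisms are combined.  Haplotype-window matching slides a 100-SNV
window (50-SNV step) along each chromosome and checks each child haplotype
for a perfect match against the four parental haplotypes; an origin label is
emitted only when the two child haplotypes match exactly one parent each,
complementarily.  A window without such an unambiguous complementary match
sets *all* of its sites to missing — including sites an overlapping window
matched — so phase-switch errors surface as missing data, never as wrong
assignments.  Sites left missing are then passed to per-SNV Mendelian
recovery, which assigns origin wherever one configuration of the child's two
alleles is impossible given the parental genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "match_windows",
    "mendelian_recover",
    "assign_parent_of_origin",
    "read_trio_vcf",
]

# origin codes for the child's first emitted haplotype
MISSING, MAT, PAT = 0, 1, 2
_STATUS = {0: "missing", 1: "window_match", 2: "mendelian"}


def _window_grid(n_sites: int, window_size: int, slide: int) -> tuple[np.ndarray, np.ndarray]:
    """Window [start, end) index pairs; a trailing shortened window covers the tail."""
    if n_sites <= window_size:
        return np.array([0]), np.array([n_sites])
    starts = np.arange(0, n_sites - window_size + 1, slide)
    ends = starts + window_size
    if ends[-1] < n_sites:
        starts = np.append(starts, starts[-1] + slide)
        ends = np.append(ends, n_sites)
    return starts, ends


def match_windows(
    child_haplotypes: np.ndarray,
    mother_haplotypes: np.ndarray,
    father_haplotypes: np.ndarray,
    window_size: int = 100,
    slide: int = 50,
) -> np.ndarray:
    """Per-site origin of the child's first haplotype: MAT, PAT or MISSING.

    All three inputs are (2, n_sites) arrays over the same ordered SNV index.
    The second haplotype's origin is the complement wherever assigned.
    """
    child = np.asarray(child_haplotypes)
    mother = np.asarray(mother_haplotypes)
    father = np.asarray(father_haplotypes)
    if not (child.shape == mother.shape == father.shape) or child.ndim != 2:
        raise ValueError("haplotype arrays must share shape (2, n_sites)")
    n_sites = child.shape[1]
    starts, ends = _window_grid(n_sites, window_size, slide)

    # cumulative mismatch counts: child hap c vs parental hap p
    parents = np.stack([mother[0], mother[1], father[0], father[1]])  # (4, V)
    mism = child[:, None, :] != parents[None, :, :]  # (2, 4, V)
    cs = np.zeros((2, 4, n_sites + 1), dtype=np.int64)
    np.cumsum(mism, axis=2, out=cs[:, :, 1:])
    nmis = cs[:, :, ends] - cs[:, :, starts]  # (2, 4, W)

    match_m = (nmis[:, 0] == 0) | (nmis[:, 1] == 0)  # (2, W)
    match_f = (nmis[:, 2] == 0) | (nmis[:, 3] == 0)
    lab = np.where(match_f & ~match_m, PAT, np.where(match_m & ~match_f, MAT, MISSING))
    ok = (lab[0] != MISSING) & (lab[1] != MISSING) & (lab[0] != lab[1])

    def _coverage(which: np.ndarray) -> np.ndarray:
        ev = np.zeros(n_sites + 1, dtype=np.int64)
        np.add.at(ev, starts[which], 1)
        np.add.at(ev, ends[which], -1)
        return np.cumsum(ev[:-1])

    n_fail = _coverage(~ok)
    n_pat = _coverage(ok & (lab[0] == PAT))
    n_mat = _coverage(ok & (lab[0] == MAT))
    origin = np.where(
        (n_fail == 0) & (n_pat > 0) & (n_mat == 0),
        PAT,
        np.where((n_fail == 0) & (n_mat > 0) & (n_pat == 0), MAT, MISSING),
    )
    return origin.astype(np.int8)


def mendelian_recover(
    child_dosage: np.ndarray,
    mother_dosage: np.ndarray,
    father_dosage: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNV Mendelian origin for child-heterozygous biallelic sites.

    Dosages are alt-allele counts (0, 1, 2; negative = missing genotype).
    Returns ``(pat_is_alt, assigned)`` boolean arrays: where ``assigned`` is
    False the site stays missing (uninformative double-het or a
    Mendelian-inconsistent trio).
    """
    c = np.asarray(child_dosage)
    m = np.asarray(mother_dosage)
    f = np.asarray(father_dosage)
    valid = (c == 1) & (m >= 0) & (f >= 0)
    m_has_ref, m_has_alt = m <= 1, m >= 1
    f_has_ref, f_has_alt = f <= 1, f >= 1
    opt_pat_ref = f_has_ref & m_has_alt  # paternal=ref, maternal=alt possible
    opt_pat_alt = f_has_alt & m_has_ref
    pat_is_alt = valid & opt_pat_alt & ~opt_pat_ref
    assigned = valid & (opt_pat_alt ^ opt_pat_ref)
    return pat_is_alt, assigned


def _dosage(h: np.ndarray) -> np.ndarray:
    return h[0].astype(np.int16) + h[1].astype(np.int16)


@dataclass
class TrioGenotypes:
    """Phased biallelic genotypes for one set of trios on one SNV index."""

    chrom: np.ndarray  # (V,) chromosome per site
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    mother: np.ndarray  # (S, 2, V)
    father: np.ndarray
    child: np.ndarray
    sample_ids: list[str]


def assign_parent_of_origin(
    trios,
    window_size: int = 100,
    slide: int = 50,
) -> pd.DataFrame:
    """PofO call table for every child-heterozygous biallelic SNV.

    ``trios`` is a :class:`TrioGenotypes` (or an object with the same
    attributes, e.g. a simulated :class:`~imprintseq.simulate.TrioHaplotypes`
    plus sample ids).  Window matching is applied per chromosome first
    (chromosomes with fewer than ``window_size`` SNVs fall back to
    Mendelian-only assignment); sites left missing go to Mendelian recovery.

    Returns columns chrom, pos, sample, paternal_allele, maternal_allele,
    status in {window_match, mendelian, missing}.
    """
    chrom = np.asarray(getattr(trios, "chrom"))
    positions = np.asarray(trios.positions)
    if chrom.ndim == 0:
        chrom = np.full(positions.size, str(chrom))
    sample_ids = getattr(trios, "sample_ids", None)
    if sample_ids is None:
        sample_ids = [f"trio{i:03d}" for i in range(trios.mother.shape[0])]
    ref, alt = np.asarray(trios.ref), np.asarray(trios.alt)
    n_samples = trios.mother.shape[0]

    frames = []
    for ch in pd.unique(chrom):
        idx = np.where(chrom == ch)[0]
        v = idx.size
        use_windows = v >= window_size
        for s in range(n_samples):
            c, m, f = trios.child[s][:, idx], trios.mother[s][:, idx], trios.father[s][:, idx]
            het = c[0] != c[1]
            if not het.any():
                continue
            origin = (
                match_windows(c, m, f, window_size, slide)
                if use_windows
                else np.zeros(v, dtype=np.int8)
            )
            pat_is_alt = np.zeros(v, dtype=bool)
            status = np.zeros(v, dtype=np.int8)
            win = het & (origin != MISSING)
            # paternal allele = allele on whichever child hap the window labeled paternal
            pat_is_alt[win] = np.where(origin[win] == PAT, c[0, win], c[1, win]) == 1
            status[win] = 1
            todo = het & ~win
            if todo.any():
                mi, ai = mendelian_recover(_dosage(c)[todo], _dosage(m)[todo], _dosage(f)[todo])
                t_idx = np.where(todo)[0]
                pat_is_alt[t_idx[ai]] = mi[ai]
                status[t_idx[ai]] = 2
            hsel = np.where(het)[0]
            st = status[hsel]
            pia = pat_is_alt[hsel]
            pat_allele = np.where(st > 0, np.where(pia, alt[idx][hsel], ref[idx][hsel]), ".")
            mat_allele = np.where(st > 0, np.where(pia, ref[idx][hsel], alt[idx][hsel]), ".")
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": ch,
                        "pos": positions[idx][hsel],
                        "sample": sample_ids[s],
                        "paternal_allele": pat_allele,
                        "maternal_allele": mat_allele,
                        "status": np.array(["missing", "window_match", "mendelian"])[st],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "sample", "paternal_allele", "maternal_allele", "status"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(drop=True)


def read_trio_vcf(path, trios: list[tuple[str, str, str]]) -> TrioGenotypes:
    """Load phased biallelic SNVs for (mother, father, child) sample triples.

    Multi-allelic sites and indels are excluded up front.  Raises if any
    named sample is absent from the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for triple in trios:
        for name in triple:
            if name not in samples:
                raise ValueError(f"trio member {name!r} not found in VCF")
    col = {name: samples.index(name) for triple in trios for name in triple}
    chroms, poss, refs, alts = [], [], [], []
    gts: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        g = np.array([row[:2] for row in var.genotypes], dtype=np.int8)
        gts.append(g)
    geno = np.stack(gts, axis=2) if gts else np.zeros((len(samples), 2, 0), dtype=np.int8)
    n_tr = len(trios)

    def _stack(role: int) -> np.ndarray:
        return np.stack([geno[col[trios[t][role]]] for t in range(n_tr)])

    return TrioGenotypes(
        chrom=np.asarray(chroms),
        positions=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs),
        alt=np.asarray(alts),
        mother=_stack(0),
        father=_stack(1),
        child=_stack(2),
        sample_ids=[c for _, _, c in trios],
    )
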