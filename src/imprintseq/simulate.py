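"""Synthetic trio cohorts with known imprinting truth.

The generator reproduces the simulation scheme used to benchmark the two
statistical tests: per-gene mean expression drawn from the level mixture
{2, 10, 20, 50, 100, 500} with proportions {0.5, 0.2, 0.1, 0.1, 0.07, 0.03},
negative-binomial counts with dispersion 0.4 (variance mu + 0.4*mu^2),
imprinting modeled as a 2-fold change on the paternal label in 1% of genes,
and cohort sizes defaulting to 138 individuals / 24,597 genes.  On top of
the count layer it simulates phased trio haplotypes with controllable
phase-switch errors, optional reference bias, and skewed X inactivation, so
that every downstream stage can be validated against emitted truth.

The truth tables are emitted *alongside* the data and are never read by the
analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "TrioHaplotypes",
    "Cohort",
    "simulate_trio_haplotypes",
    "simulate_gene_counts",
    "simulate_allelic_counts",
    "simulate_x_counts",
    "simulate_cohort",
    "zinb_sample",
]

# labels for the child's two emitted haplotypes
MATERNAL, PATERNAL = 0, 1


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults are the benchmark conditions: level mixture with dispersion 0.4,
    2-fold paternal change in 1% of genes, 138 individuals, 24,597 genes.
    ``zero_inflation`` defaults to 0 (the benchmark scheme is plain NB); it
    is exposed for stress-testing the zero-inflated model.
    """

    n_genes: int = 24_597
    n_samples: int = 138
    count_levels: tuple[float, ...] = (2, 10, 20, 50, 100, 500)
    level_proportions: tuple[float, ...] = (0.5, 0.2, 0.1, 0.1, 0.07, 0.03)
    dispersion: float = 0.4
    fold_change: float = 2.0
    imprinted_fraction: float = 0.01
    zero_inflation: float = 0.0
    snvs_per_gene_mean: float = 5.0  # SNVs per gene ~ 1 + Poisson(mean)
    phase_switch_rate: float = 0.0  # per 100-SNV block
    switch_block: int = 100
    ref_bias_genes: int = 0
    ref_bias_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.count_levels) != len(self.level_proportions):
            raise ValueError("count_levels and level_proportions length mismatch")
        if abs(sum(self.level_proportions) - 1.0) > 1e-9:
            raise ValueError("level_proportions must sum to 1")
        if any(l <= 0 for l in self.count_levels):
            raise ValueError("all count levels must be > 0")
        if not 0.0 <= self.imprinted_fraction <= 1.0:
            raise ValueError("imprinted_fraction must be in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TruthTable:
    """Ground truth emitted with a simulated dataset (never read by the pipeline).

    ``genes`` has one row per simulated gene: gene_id, is_imprinted,
    direction, expression level, ref_bias flag.  Haplotype truth lives in
    the arrays: ``maternal_allele``/``paternal_allele`` give the true
    transmitted alleles per (sample, site), ``hap_parent`` the parent of the
    child's emitted haplotype *before* switch injection, and ``switches``
    the injected switch-block starts per sample.
    """

    genes: pd.DataFrame | None = None
    maternal_allele: np.ndarray | None = None  # (S, V) 0/1
    paternal_allele: np.ndarray | None = None
    hap_parent: np.ndarray | None = None  # (S, 2) MATERNAL/PATERNAL per emitted hap
    switches: list[np.ndarray] = field(default_factory=list)
    xcir: np.ndarray | None = None


@dataclass
class TrioHaplotypes:
    """Phased genotypes for n trios over one ordered SNV index."""

    chrom: str
    positions: np.ndarray  # (V,) 1-based
    ref: np.ndarray  # (V,) allele symbols
    alt: np.ndarray
    mother: np.ndarray  # (S, 2, V) 0/1
    father: np.ndarray
    child: np.ndarray  # emitted (possibly switch-corrupted) child haplotypes

    @property
    def n_samples(self) -> int:
        return self.mother.shape[0]

    @property
    def n_snvs(self) -> int:
        return self.positions.size


def zinb_sample(rng: np.random.Generator, mu, phi: float, pi: float, size=None):
    """Zero-inflated NB draws with mean mu (of the NB part) and variance mu+phi*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if size is None:
        size = mu.shape
    mu = np.broadcast_to(mu, size)
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    else:
        lam = mu
    y = rng.poisson(lam)
    if pi > 0:
        y = np.where(rng.random(size) < pi, 0, y)
    return y.astype(np.int64)


def simulate_trio_haplotypes(
    config: SimulationConfig,
    n_snvs: int,
    allele_freqs=None,
    *,
    chrom: str = "1",
    positions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TrioHaplotypes, TruthTable]:
    """Draw phased trio genotypes for ``config.n_samples`` trios.

    Four parental haplotypes are drawn independently per site from
    ``allele_freqs`` (default: Uniform(0.05, 0.95) per site, mimicking the
    common-variant ascertainment of imputed panels).  Each child inherits
    one whole maternal and one whole paternal haplotype (no recombination),
    emitted in random order.  With probability ``config.phase_switch_rate``
    per ``switch_block`` SNVs, the emitted child phasing swaps from that
    block onward; the truth records the unswapped transmission.
    """
    if n_snvs < 1:
        raise ValueError("n_snvs must be >= 1")
    rng = config.rng() if rng is None else rng
    if allele_freqs is None:
        freqs = rng.uniform(0.05, 0.95, size=n_snvs)
    else:
        freqs = np.broadcast_to(np.asarray(allele_freqs, dtype=float), (n_snvs,))
        bad = np.where((freqs < 0) | (freqs > 1))[0]
        if bad.size:
            raise ValueError(f"allele frequency outside [0, 1] at site index {bad[0]}")
    n = config.n_samples
    mother = (rng.random((n, 2, n_snvs)) < freqs).astype(np.int8)
    father = (rng.random((n, 2, n_snvs)) < freqs).astype(np.int8)
    m_idx = rng.integers(0, 2, size=n)
    f_idx = rng.integers(0, 2, size=n)
    mat_hap = mother[np.arange(n), m_idx]  # (S, V) true transmitted
    pat_hap = father[np.arange(n), f_idx]

    hap_parent = np.empty((n, 2), dtype=np.int8)
    child = np.empty((n, 2, n_snvs), dtype=np.int8)
    order = rng.integers(0, 2, size=n)  # which emitted slot holds the maternal hap
    switches: list[np.ndarray] = []
    n_blocks = int(np.ceil(n_snvs / config.switch_block))
    for s in range(n):
        hap_parent[s, order[s]] = MATERNAL
        hap_parent[s, 1 - order[s]] = PATERNAL
        child[s, order[s]] = mat_hap[s]
        child[s, 1 - order[s]] = pat_hap[s]
        hit = rng.random(n_blocks) < config.phase_switch_rate
        starts = np.where(hit)[0] * config.switch_block
        switches.append(starts)
        # cumulative swap: each switch toggles the phase from its block onward
        if starts.size:
            flip = np.zeros(n_snvs, dtype=bool)
            for b in starts:
                flip[b:] = ~flip[b:]
            swapped = child[s, ::-1, :]
            child[s] = np.where(flip[None, :], swapped, child[s])

    if positions is None:
        positions = np.arange(1, n_snvs + 1, dtype=np.int64)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_snvs)]
    alt_shift = rng.integers(1, 4, size=n_snvs)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
    trio = TrioHaplotypes(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        mother=mother,
        father=father,
        child=child,
    )
    truth = TruthTable(
        maternal_allele=mat_hap,
        paternal_allele=pat_hap,
        hap_parent=hap_parent,
        switches=switches,
    )
    return trio, truth


def simulate_gene_counts(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Gene-level paired counts: (pat, mat) matrices (genes x samples) + truth genes.

    Per gene a mean level is drawn from the level mixture; per sample the
    maternal count is ZINB(mu) and the paternal count ZINB(fold_change*mu)
    for imprinted genes (ZINB(mu) otherwise).
    """
    rng = config.rng() if rng is None else rng
    g, s = config.n_genes, config.n_samples
    levels = rng.choice(config.count_levels, size=g, p=config.level_proportions)
    n_imp = int(round(config.imprinted_fraction * g))
    imprinted = np.zeros(g, dtype=bool)
    if n_imp:
        imprinted[rng.choice(g, size=n_imp, replace=False)] = True
    mu_mat = np.broadcast_to(levels[:, None], (g, s))
    mu_pat = np.broadcast_to(
        np.where(imprinted, config.fold_change * levels, levels)[:, None], (g, s)
    )
    mat = zinb_sample(rng, mu_mat, config.dispersion, config.zero_inflation)
    pat = zinb_sample(rng, mu_pat, config.dispersion, config.zero_inflation)
    ref_bias = np.zeros(g, dtype=bool)
    if config.ref_bias_genes:
        candidates = np.where(~imprinted)[0]
        chosen = rng.choice(candidates, size=min(config.ref_bias_genes, candidates.size), replace=False)
        ref_bias[chosen] = True
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(g)],
            "is_imprinted": imprinted,
            "direction": np.where(imprinted, "paternal", ""),
            "level": levels,
            "ref_bias": ref_bias,
        }
    )
    return pat, mat, genes


def simulate_allelic_counts(
    config: SimulationConfig,
    trio: TrioHaplotypes,
    truth: TruthTable,
    gene_snv_index: list[np.ndarray],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-gene paired totals and split them across child-het SNVs.

    Gene totals come from :func:`simulate_gene_counts` and are allocated to
    the gene's child-heterozygous SNVs by an equal-weight multinomial per
    sample; ref/alt labels derive from the sampled alleles; ref-bias genes
    have ``ref_bias_strength`` of alt reads relabeled as ref (binomial
    thinning).  Returns the long count table (chrom, pos, sample, ref_count,
    alt_count, strand); per-gene truth is stored on ``truth.genes``.
    """
    rng = config.rng() if rng is None else rng
    pat_tot, mat_tot, genes = simulate_gene_counts(config, rng)
    truth.genes = genes

    het = trio.child[:, 0, :] != trio.child[:, 1, :]  # (S, V)
    pat_allele = truth.paternal_allele  # (S, V) 0/1
    n_samples = trio.n_samples
    rows: dict[str, list] = {k: [] for k in ("pos_idx", "sample", "ref_count", "alt_count")}
    pat_true = np.zeros_like(pat_tot)
    mat_true = np.zeros_like(mat_tot)
    for gi, snv_idx in enumerate(gene_snv_index):
        if snv_idx.size == 0:
            continue
        strength = config.ref_bias_strength if genes.loc[gi, "ref_bias"] else 0.0
        for s in range(n_samples):
            het_idx = snv_idx[het[s, snv_idx]]
            if het_idx.size == 0:
                continue  # sample uninformative for this gene; counts are lost
            pt, mt = int(pat_tot[gi, s]), int(mat_tot[gi, s])
            pat_true[gi, s], mat_true[gi, s] = pt, mt
            probs = np.full(het_idx.size, 1.0 / het_idx.size)
            pat_site = rng.multinomial(pt, probs)
            mat_site = rng.multinomial(mt, probs)
            is_pat_alt = pat_allele[s, het_idx] == 1
            ref_c = np.where(is_pat_alt, mat_site, pat_site)
            alt_c = np.where(is_pat_alt, pat_site, mat_site)
            if strength > 0:
                moved = rng.binomial(alt_c, strength)
                ref_c = ref_c + moved
                alt_c = alt_c - moved
            keep = (ref_c + alt_c) > 0
            rows["pos_idx"].extend(het_idx[keep].tolist())
            rows["sample"].extend([s] * int(keep.sum()))
            rows["ref_count"].extend(ref_c[keep].tolist())
            rows["alt_count"].extend(alt_c[keep].tolist())
    truth.genes["true_pat_total"] = pat_true.sum(axis=1)
    truth.genes["true_mat_total"] = mat_true.sum(axis=1)
    counts = pd.DataFrame(
        {
            "chrom": trio.chrom,
            "pos": trio.positions[np.asarray(rows["pos_idx"], dtype=int)],
            "sample": np.array([f"trio{s:03d}" for s in rows["sample"]]),
            "ref_count": np.asarray(rows["ref_count"], dtype=np.int64),
            "alt_count": np.asarray(rows["alt_count"], dtype=np.int64),
            "strand": ".",
        }
    )
    return counts.sort_values(["pos", "sample"], kind="stable").reset_index(drop=True)


def simulate_x_counts(
    config: SimulationConfig,
    xcir_values,
    *,
    n_genes: int | None = None,
    imprinted: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, TruthTable]:
    """Gene-level chrX counts for females with per-sample inactivation ratios.

    Non-imprinted X genes emit paternal ~ ZINB(xcir*mu) and maternal ~
    ZINB((1-xcir)*mu) per female.  Paternally imprinted X genes transcribe
    only the paternal copy, which is active in an ``xcir`` fraction of
    cells: pat ~ ZINB(xcir*mu), mat = 0.
    """
    xcir = np.asarray(xcir_values, dtype=float)
    if np.any((xcir < 0) | (xcir > 1)):
        raise ValueError("xcir values must lie in [0, 1]")
    rng = config.rng() if rng is None else rng
    g = n_genes if n_genes is not None else config.n_genes
    if imprinted is None:
        imprinted = np.zeros(g, dtype=bool)
    levels = rng.choice(config.count_levels, size=g, p=config.level_proportions)
    mu = levels[:, None]
    mu_pat = xcir[None, :] * mu
    mu_mat = np.where(imprinted[:, None], 0.0, (1.0 - xcir[None, :]) * mu)
    pat = zinb_sample(rng, np.maximum(mu_pat, 1e-12), config.dispersion, config.zero_inflation)
    mat = np.where(
        mu_mat > 0,
        zinb_sample(rng, np.maximum(mu_mat, 1e-12), config.dispersion, config.zero_inflation),
        0,
    )
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "gene_id": [f"XG{i:04d}" for i in range(g)],
                "is_imprinted": imprinted,
                "direction": np.where(imprinted, "paternal", ""),
                "level": levels,
                "ref_bias": False,
            }
        ),
        xcir=xcir,
    )
    return pat, mat, truth


@dataclass
class Cohort:
    """A fully simulated study: genotypes, counts, gene models and truth."""

    config: SimulationConfig
    trio: TrioHaplotypes
    genes: pd.DataFrame  # chrom, start, end, strand, gene_id (0-based half-open)
    counts: pd.DataFrame  # chrom, pos, sample, ref_count, alt_count, strand
    truth: TruthTable
    gene_snv_index: list[np.ndarray]

    @property
    def sample_ids(self) -> list[str]:
        return [f"trio{i:03d}" for i in range(self.trio.n_samples)]


def simulate_cohort(
    config: SimulationConfig,
    *,
    chrom: str = "1",
    gene_length: int = 10_000,
    gene_gap: int = 5_000,
    allele_freqs=None,
) -> Cohort:
    """End-to-end synthetic study on one chromosome.

    Genes are laid back-to-back with fixed length/gap; each carries
    1 + Poisson(snvs_per_gene_mean) SNVs at uniform positions; trio
    haplotypes are drawn over the pooled SNV set and gene totals are split
    onto child-heterozygous SNVs.
    """
    rng = config.rng()
    g = config.n_genes
    starts = np.arange(g, dtype=np.int64) * (gene_length + gene_gap)
    ends = starts + gene_length
    strands = np.where(rng.random(g) < 0.5, "+", "-")
    genes = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "strand": strands,
            "gene_id": [f"G{i:05d}" for i in range(g)],
        }
    )
    n_snv_gene = 1 + rng.poisson(config.snvs_per_gene_mean, size=g)
    pos_list = []
    for gi in range(g):
        # distinct positions within the gene body (1-based)
        p = rng.choice(gene_length, size=min(n_snv_gene[gi], gene_length), replace=False)
        pos_list.append(np.sort(starts[gi] + 1 + p))
    positions = np.concatenate(pos_list) if pos_list else np.zeros(0, dtype=np.int64)
    offsets = np.cumsum([0] + [p.size for p in pos_list])
    gene_snv_index = [np.arange(offsets[i], offsets[i + 1]) for i in range(g)]

    if positions.size == 0:
        empty = np.zeros((config.n_samples, 2, 0), dtype=np.int8)
        trio = TrioHaplotypes(
            chrom=chrom,
            positions=positions,
            ref=np.zeros(0, dtype="<U1"),
            alt=np.zeros(0, dtype="<U1"),
            mother=empty,
            father=empty.copy(),
            child=empty.copy(),
        )
        truth = TruthTable(
            maternal_allele=np.zeros((config.n_samples, 0), dtype=np.int8),
            paternal_allele=np.zeros((config.n_samples, 0), dtype=np.int8),
            hap_parent=np.tile([MATERNAL, PATERNAL], (config.n_samples, 1)).astype(np.int8),
            switches=[np.zeros(0, dtype=int)] * config.n_samples,
        )
    else:
        trio, truth = simulate_trio_haplotypes(
            config, positions.size, allele_freqs, chrom=chrom, positions=positions, rng=rng
        )
    counts = simulate_allelic_counts(config, trio, truth, gene_snv_index, rng=rng)
    return Cohort(
        config=config,
        trio=trio,
        genes=genes,
        counts=counts,
        truth=truth,
        gene_snv_index=gene_snv_index,
    )
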