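# Methods

## Problem and model

At a heterozygous SNV in a child whose genotypes are phased against both
parents, every RNA-Seq read can be attributed to the paternally or
maternally transmitted allele. Summing these counts over all SNVs of a
testing unit gives, per individual *i*, a pair (patᵢ, matᵢ). Genomic
imprinting predicts a consistent population-wide bias of patᵢ against
matᵢ; everything else (eQTLs in cis, random monoallelic expression,
technical noise) is expected to be symmetric in parental origin across
unrelated trios. The package therefore tests, per unit, the null that the
paired differences patᵢ − matᵢ are symmetric about zero.

## Parent-of-origin assignment

Window matching: along each chromosome's ordered SNV index, windows of
100 SNVs advance in 50-SNV steps (a shortened final window covers the
tail). Within a window each child haplotype is compared for a *perfect*
match against the four parental haplotypes. Origin is assigned only when
the two child haplotypes match exactly one parent each, complementarily; a
window without such a match — which is what a phase-switch error produces
— sets **all** of its sites to missing, including sites an overlapping
intact window matched. This is deliberately conservative: with whole-
haplotype transmission the only way a wrong label could arise is through
an undetected double error, and blanking whole windows keeps the wrong-
assignment rate at zero in all simulations (errors become missingness).
Sites left missing go to per-SNV Mendelian recovery: if only one
configuration of the child's two alleles is compatible with the parental
genotypes (e.g. one parent homozygous), origin follows; double-het trios
stay missing; Mendelian-inconsistent sites stay missing. Chromosomes with
fewer SNVs than one window skip matching and use Mendelian rules only.

Windows are compared at the haplotype level, so the method also assigns
origin at sites where all three genotypes are heterozygous — the sites
Mendelian logic can never resolve.

## Unique gene fragments

Overlapping transcripts confound per-gene aggregation, so gene bodies
(min start to max end over a gene's records — intronic SNVs count) are cut
at every gene start/end breakpoint and maximal runs with an identical
covering gene set become one unique gene fragment (UGF). Fragments are
non-overlapping, their union equals the union of gene bodies, and the
construction is idempotent. Multi-gene (shared) fragments are retained as
testable units, flagged by `n_genes`; per-gene reporting picks the UGF
with the smallest p value. For stranded libraries, UGF sets are built per
strand so antisense pairs (one paternally, one maternally expressed) are
separated. Coordinates are 0-based half-open internally; GTF input is
converted at the boundary.

## Counting rules

SNVs falling in any exclusion mask (low mappability, common CNVs,
segmental duplications, simple repeats) are removed with a per-site log of
the masks hit. Ref/alt counts are flipped into pat/mat using the PofO
call; sites with missing PofO are excluded from parental sums but kept in
the ref/alt tally used by the reference-bias screen (more data, no
directional assumption). A unit enters testing when at least 10 % of
individuals have ≥ 1 informative read (inclusive threshold, configurable).
Per-individual paternal ratios are computed from the aggregated counts,
pat/(pat+mat), not by averaging per-SNV ratios; the unit-level PatRatio is
their mean over informative individuals.

## Paired Wilcoxon signed-rank test

Zero differences are discarded (classic Wilcoxon); |differences| are
midranked. With n ≤ 25 nonzero pairs the two-sided p comes from the exact
sign-permutation distribution of the signed-rank sum, computed by dynamic
programming over the 2n-scale integer rank sums; p = min(1, 2·min(P(W ≤
w), P(W ≥ w))). Above n = 25 the normal approximation with tie-corrected
variance (no continuity correction) is used; it matches
`scipy.stats.wilcoxon(method="approx")` exactly and the exact path matches
full enumeration to < 1e-9.

## Paired ZINB empirical-Bayes test

The second test fits, per unit, the paired zero-inflated
negative-binomial model

    y_ij ~ ZINB(mu_ij, phi, pi),  log mu_ij = alpha_i + beta * patmat_j

with one intercept per individual (absorbing expression-level differences
between people, the role of a random individual effect) and a single
parent-of-origin coefficient β; the p value is a likelihood-ratio test of
β = 0 against χ²₁. Three implementation points matter:

- **Empirical-Bayes moments.** The NB dispersion (variance μ + φμ²) is
  estimated per unit by method of moments from the two parental count
  vectors, and shrunk toward the cohort-pooled value with weight
  n/(n + n₀), n₀ = 20 by default. Zero inflation is the shrunk excess of
  observed zeros over the NB prediction, default prior 0 (the benchmark
  generator emits plain NB counts). Both can be fixed explicitly.
- **Profile fitting.** For each β the intercepts are profiled by Fisher
  scoring (for Poisson data this is exactly conditioning on the pair
  totals, i.e. a binomial test of the paternal fraction — a property used
  as a cross-check in the tests). β itself takes Newton steps with the
  *profile* information v_pat·v_mat/(v_pat+v_mat) per pair, which handles
  complete separation (one parent silent): β walks to a ±15 cap where the
  profile likelihood has plateaued, and convergence is declared there.
  Units that still fail to converge report p = 1 with a flag — a
  non-converged fit is never allowed to become a discovery.
- **Cox–Reid adjustment.** Profiling one nuisance intercept per individual
  (two observations each) biases the raw LRT slightly downward. Both fits
  subtract half the log-determinant of the intercept information (the
  Cox–Reid adjusted profile likelihood, the same device edgeR uses for
  dispersion estimation), which restores χ²₁ calibration: on the 2000-gene
  null benchmark the p distribution is indistinguishable from uniform
  (KS) and λ ≈ 1.

This model is a deliberate, documented stand-in for a fully Bayesian
spike-and-slab ZINB treatment; it reproduces that method's role (power at
low expression and small informative-sample counts, zero-inflation
robustness) without INLA-style machinery, and BH-FDR is applied uniformly
to both tests rather than mixing FDR flavors.

## FDR, confidence classes, screens

Benjamini–Hochberg q values at 10 % FDR define significance. Units
significant in both tests are high confidence, in exactly one low
confidence. Aggregated ref vs alt counts per unit are compared with a
two-sided paired WSR at 5 % FDR; flagged units are removed from reported
imprinted sets, since reads preferentially matching the reference genome
indicate alignment artifacts rather than imprinting. Genomic inflation is
λ = median(χ²₁-quantile(1 − p)) / median(χ²₁); the exact χ²₁ median is
used so a point mass at p = 0.5 gives λ = 1 identically.

## Window scan and enrichment

The annotation-free scan pools oriented counts in 25 kb windows sliding by
5 kb (grid anchored at 0, configurable offset), runs the WSR test per
window over per-individual sums, and BH-corrects across scored windows;
windows without informative SNVs are skipped, and the unit-level 10 %
informativeness rule is reused. The enrichment test takes non-overlapping
25 kb bins within ±250 kb of strongly imprinted genes (PatRatio ≤ 0.1 or
≥ 0.9), dropping bins that overlap a *different* strong gene, and compares
mean(−log₁₀ p) of that set against draws of equally many bins from all
scored bins; p = (r + 1)/(n_perm + 1), so 1999 permutations give a minimum
attainable p of 0.0005. The statistic and the informativeness requirement
are parameters, since reasonable alternatives exist.

## Chromosome X

Random X inactivation, not imprinting, dominates female chrX allelic
ratios. Per female, XCIR = Σ patᵢ / (Σ patᵢ + Σ matᵢ) pooled over
X-linked genes; females with XCIR < 0.2 or > 0.8 (strict; boundary values
kept) are excluded — in cell lines this doubles as a clonality filter, and
the retained-female subset can be fed back through the autosomal driver
for a clonality-robustness re-analysis. In retained females, paternal
counts are weighted by 0.5/XCIR and maternal by 0.5/(1 − XCIR), then
renormalized to the original pair total with half-even rounding (totals
preserved exactly), and the WSR + BH machinery runs as on autosomes. The
weighting formula itself is a package design choice — isolated in
`adjust_counts` so alternatives can be swapped — because "adjusting by the
XCIR" admits several formalizations; this one maps a non-imprinted gene to
an expected adjusted ratio of 0.5 for any XCIR, and is the identity at
XCIR = 0.5.

## Synthetic cohorts

The generator emulates the benchmark simulation scheme: per-gene mean
expression from levels {2, 10, 20, 50, 100, 500} with proportions
{0.5, 0.2, 0.1, 0.1, 0.07, 0.03} (mixture mean ≈ 32), NB dispersion fixed
at 0.4, imprinting as a 2-fold change on the paternal label in 1 % of
genes, and default cohort sizes of 138 individuals and 24,597 genes.
Zero-inflation weight defaults to 0 and is exposed for stress tests. On
top of the count layer: four parental haplotypes drawn i.i.d. per site
(allele frequencies default to U(0.05, 0.95), mimicking common-variant
panels), whole-haplotype transmission without recombination, phase-switch
errors injected at 100-SNV block boundaries (aligned with the matcher's
window so recovery behavior is interpretable), gene totals split over a
sample's heterozygous SNVs by an equal-weight multinomial (irrelevant to
gene-level tests, only to window-scan realism), reference bias as binomial
relabeling of alt reads to ref, and chrX counts scaled by per-female
inactivation ratios. SNVs per gene are 1 + Poisson(5) by default — an
arbitrary but configurable choice. Truth tables (imprinting flags,
transmitted haplotypes, switch positions, bias flags, XCIR) are emitted
alongside the data and never read by any analysis module (enforced by a
test).

What the generator does *not* emulate: read-level artifacts (mapping
bias beyond the simple relabeling model, base errors, duplicates),
recombination, linkage structure between sites, covariates such as age or
sex, library-size variation between individuals, and isoform structure.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to every
real-data pathology; the mask filters and the reference-bias screen exist
precisely because real data violate the clean model.

## Numerical choices and problem sizes

Exact WSR below 25 pairs, normal approximation above; β capped at |β| ≤ 15;
Fisher-scoring steps clipped at ±2 with convergence at step < 1e-7; BH via
statsmodels; p values clipped at 1e-300 before the χ² quantile transform.
Validation runs use cohorts of 2,000 genes at 20–138 individuals, 30 trios
× 20,000 SNVs for assignment soundness, and a few-hundred-gene cohort for
the end-to-end and window-scan checks — sizes at which every Monte-Carlo
tolerance in the tests (3-SE bands, KS at α = 0.01) is meaningful while
the whole suite stays fast.

## Known limitations

- The ZINB stand-in shares the two tests' data, so "high confidence" is
  not an independent replication; it filters test-specific pathologies.
- Mendelian recovery inside blanked windows trusts single-SNV genotypes;
  genotyping error there would produce wrong (not missing) assignments —
  upstream QC is assumed.
- The window scan reuses sites across overlapping windows; neighboring
  window p values are strongly dependent, and BH across windows is
  therefore approximate (the enrichment test uses non-overlapping bins for
  this reason).
- Multi-allelic SNVs and indels are excluded up front.
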