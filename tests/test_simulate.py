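"""Synthetic-cohort generator: determinism, distributional targets, truth separation."""

import filecmp
import inspect

import numpy as np
import pandas as pd
import pytest

from imprintseq import annotation, counts as counts_mod, model, pofo, windows, xchrom
from imprintseq.cohort_io import read_counts, write_cohort
from imprintseq.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_gene_counts,
    simulate_trio_haplotypes,
    simulate_x_counts,
)


class TestConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(level_proportions=(0.5, 0.2, 0.1, 0.1, 0.07, 0.02))

    def test_bad_fold_change_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fold_change=0.0)

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(count_levels=(0, 1), level_proportions=(0.5, 0.5))


class TestTrioHaplotypes:
    def test_no_switches_child_copies_a_parent(self):
        cfg = SimulationConfig(n_samples=10, phase_switch_rate=0.0, seed=1)
        trio, truth = simulate_trio_haplotypes(cfg, 500)
        for s in range(10):
            for h in range(2):
                parents = np.vstack([trio.mother[s], trio.father[s]])
                assert any(np.array_equal(trio.child[s, h], p) for p in parents)

    def test_monomorphic_sites_all_hom_ref(self):
        cfg = SimulationConfig(n_samples=5, seed=2)
        trio, _ = simulate_trio_haplotypes(cfg, 100, allele_freqs=0.0)
        for arr in (trio.mother, trio.father, trio.child):
            assert not arr.any()

    def test_het_fraction_matches_binomial_expectation(self):
        # child het prob = 2p(1-p) = 0.5 at p = 0.5
        cfg = SimulationConfig(n_samples=4, seed=3)
        trio, _ = simulate_trio_haplotypes(cfg, 10_000, allele_freqs=0.5)
        het = (trio.child[:, 0, :] != trio.child[:, 1, :]).mean()
        se = np.sqrt(0.25 / (4 * 10_000))
        assert abs(het - 0.5) < 3 * se

    def test_bad_allele_freq_names_site(self):
        cfg = SimulationConfig(n_samples=2, seed=4)
        freqs = np.full(10, 0.5)
        freqs[7] = 1.5
        with pytest.raises(ValueError, match="site index 7"):
            simulate_trio_haplotypes(cfg, 10, allele_freqs=freqs)

    def test_truth_records_unswapped_transmission(self):
        cfg = SimulationConfig(n_samples=20, phase_switch_rate=0.02, seed=5)
        trio, truth = simulate_trio_haplotypes(cfg, 2000)
        # maternal + paternal truth alleles reproduce the child's genotype set
        dosage_truth = truth.maternal_allele + truth.paternal_allele
        dosage_emit = trio.child[:, 0, :] + trio.child[:, 1, :]
        assert np.array_equal(dosage_truth, dosage_emit)


class TestGeneCounts:
    def test_null_pooled_ratio_near_half(self):
        cfg = SimulationConfig(
            n_genes=500, n_samples=30, fold_change=1.0, imprinted_fraction=0.0, seed=6
        )
        pat, mat, _ = simulate_gene_counts(cfg)
        ratio = pat.sum() / (pat.sum() + mat.sum())
        assert abs(ratio - 0.5) < 3 * 0.5 / np.sqrt(pat.sum() + mat.sum())

    def test_imprinted_ratio_two_thirds(self):
        cfg = SimulationConfig(
            n_genes=300, n_samples=50, fold_change=2.0, imprinted_fraction=1.0, seed=7
        )
        pat, mat, genes = simulate_gene_counts(cfg)
        assert genes["is_imprinted"].all()
        ratio = pat.sum() / (pat.sum() + mat.sum())
        assert ratio == pytest.approx(2 / 3, abs=0.02)

    def test_mixture_mean_expression(self):
        # independent oracle: expectation of the level mixture
        cfg = SimulationConfig(n_genes=4000, n_samples=5, seed=8)
        expected = sum(l * p for l, p in zip(cfg.count_levels, cfg.level_proportions))
        _, _, genes = simulate_gene_counts(cfg)
        assert genes["level"].mean() == pytest.approx(expected, rel=0.1)


class TestXCounts:
    def test_balanced_xcir_centers_ratios(self):
        cfg = SimulationConfig(
            n_genes=50, n_samples=40, count_levels=(200,), level_proportions=(1.0,), seed=9
        )
        pat, mat, _ = simulate_x_counts(cfg, np.full(40, 0.5))
        ratios = pat.sum(1) / (pat.sum(1) + mat.sum(1))
        assert abs(ratios.mean() - 0.5) < 0.02

    def test_complete_skew_silences_maternal(self):
        cfg = SimulationConfig(
            n_genes=20, n_samples=10, count_levels=(100,), level_proportions=(1.0,), seed=10
        )
        pat, mat, _ = simulate_x_counts(cfg, np.ones(10))
        assert mat.sum() == 0
        assert pat.sum() > 0

    def test_xcir_recovered_from_counts(self):
        cfg = SimulationConfig(
            n_genes=80, n_samples=50, count_levels=(100,), level_proportions=(1.0,), seed=11
        )
        pat, mat, _ = simulate_x_counts(cfg, np.full(50, 0.7))
        obs = pat.sum(0) / (pat.sum(0) + mat.sum(0))
        # per-female pooled ratio over 80 genes x mean 100 reads
        assert abs(obs.mean() - 0.7) < 0.02

    def test_invalid_xcir_rejected(self):
        cfg = SimulationConfig(n_genes=5, n_samples=2, seed=12)
        with pytest.raises(ValueError):
            simulate_x_counts(cfg, [0.5, 1.2])


class TestCohortIO:
    def test_round_trip_and_determinism(self, tmp_path):
        cfg = SimulationConfig(n_genes=20, n_samples=5, imprinted_fraction=0.1, seed=13)
        paths1 = write_cohort(simulate_cohort(cfg), tmp_path / "a")
        paths2 = write_cohort(simulate_cohort(cfg), tmp_path / "b")
        for key in paths1:
            assert filecmp.cmp(paths1[key], paths2[key], shallow=False), key
        co = simulate_cohort(cfg)
        readback = read_counts(paths1["counts"])
        assert len(readback) == len(co.counts)
        assert readback["ref_count"].sum() == co.counts["ref_count"].sum()

    def test_empty_cohort_valid_headers(self, tmp_path):
        cfg = SimulationConfig(n_genes=0, n_samples=3, seed=14)
        paths = write_cohort(simulate_cohort(cfg), tmp_path / "empty")
        vcf_lines = paths["vcf"].read_text().splitlines()
        assert vcf_lines[0].startswith("##fileformat")
        assert vcf_lines[-1].startswith("#CHROM")
        assert len(read_counts(paths["counts"])) == 0

    def test_vcf_read_back_matches_memory(self, tmp_path):
        from imprintseq.cohort_io import cohort_trio_names
        from imprintseq.pofo import read_trio_vcf

        cfg = SimulationConfig(n_genes=15, n_samples=4, seed=15)
        co = simulate_cohort(cfg)
        paths = write_cohort(co, tmp_path / "c")
        trios = read_trio_vcf(paths["vcf"], cohort_trio_names(co))
        assert np.array_equal(trios.child, co.trio.child)
        assert np.array_equal(trios.mother, co.trio.mother)
        assert np.array_equal(trios.positions, co.trio.positions)


def test_pipeline_modules_never_read_truth():
    """Truth/emission separation: no analysis module references the TruthTable."""
    for mod in (pofo, annotation, counts_mod, model, windows, xchrom):
        assert "TruthTable" not in inspect.getsource(mod)
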