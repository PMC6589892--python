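"""Parent-of-origin assignment: window matching, Mendelian recovery, soundness."""

import numpy as np
import pandas as pd
import pytest

from imprintseq.pofo import (
    MAT,
    MISSING,
    PAT,
    assign_parent_of_origin,
    match_windows,
    mendelian_recover,
)
from imprintseq.simulate import SimulationConfig, simulate_trio_haplotypes


def truth_assignment_check(trio, truth, calls):
    """Return (assigned_fraction, n_wrong) of a call table vs simulation truth."""
    pos_index = {p: i for i, p in enumerate(trio.positions)}
    sid = {f"trio{i:03d}": i for i in range(trio.n_samples)}
    v = calls["pos"].map(pos_index).values
    s = calls["sample"].map(sid).values
    assigned = calls["status"].isin(["window_match", "mendelian"]).values
    true_sym = np.where(truth.paternal_allele[s, v] == 1, trio.alt[v], trio.ref[v])
    wrong = assigned & (calls["paternal_allele"].values != true_sym)
    return assigned.mean(), int(wrong.sum())


class TestMatchWindows:
    def _mk(self, child0, child1, m0, m1, f0, f1):
        return (
            np.array([child0, child1], dtype=np.int8),
            np.array([m0, m1], dtype=np.int8),
            np.array([f0, f1], dtype=np.int8),
        )

    def test_unique_paternal_match(self, rng):
        v = 30
        f0 = rng.integers(0, 2, v).astype(np.int8)
        m0 = 1 - f0  # maternal haps distinct from paternal
        child, mother, father = self._mk(f0, m0, m0, m0, f0, f0)
        origin = match_windows(child, mother, father, window_size=30, slide=15)
        assert np.all(origin == PAT)

    def test_identical_parents_ambiguous(self):
        h = np.ones(20, dtype=np.int8)
        child, mother, father = self._mk(h, 1 - h, h, 1 - h, h, 1 - h)
        origin = match_windows(child, mother, father, window_size=20, slide=10)
        assert np.all(origin == MISSING)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_windows(np.zeros((2, 10)), np.zeros((2, 9)), np.zeros((2, 10)))

    def test_phase_switch_blanks_spanning_windows_only(self, rng):
        v = 400
        m_hap = rng.integers(0, 2, v).astype(np.int8)
        f_hap = 1 - m_hap
        child = np.array([m_hap.copy(), f_hap.copy()])
        # inject a switch at index 200
        child[:, 200:] = child[::-1, 200:]
        mother = np.array([m_hap, m_hap])
        father = np.array([f_hap, f_hap])
        origin = match_windows(child, mother, father, window_size=100, slide=50)
        # flanks assign and never wrongly: hap0 is maternal before 200, paternal after
        assert np.all(origin[:150] == MAT)
        assert np.all(origin[250:] == PAT)
        assert np.all(origin[150:250] == MISSING)


class TestMendelianRecover:
    @pytest.mark.parametrize(
        "mother,father,expect_assigned,expect_pat_alt",
        [
            (0, 2, True, True),  # child ref/alt, mother ref hom, father alt hom
            (1, 1, False, False),  # everyone het: uninformative
            (0, 1, True, True),  # forced by maternal homozygosity
            (2, 2, False, False),  # child carries ref no parent has: inconsistent
        ],
    )
    def test_single_site_rules(self, mother, father, expect_assigned, expect_pat_alt):
        pat_is_alt, assigned = mendelian_recover(
            np.array([1]), np.array([mother]), np.array([father])
        )
        assert assigned[0] == expect_assigned
        if expect_assigned:
            assert pat_is_alt[0] == expect_pat_alt

    def test_missing_parent_genotype_stays_missing(self):
        _, assigned = mendelian_recover(np.array([1]), np.array([-1]), np.array([0]))
        assert not assigned[0]


class TestAssignParentOfOrigin:
    def test_error_free_cohort_fully_assigned_and_correct(self):
        cfg = SimulationConfig(n_samples=10, phase_switch_rate=0.0, seed=21)
        trio, truth = simulate_trio_haplotypes(cfg, 3000)
        calls = assign_parent_of_origin(trio)
        frac, wrong = truth_assignment_check(trio, truth, calls)
        assert wrong == 0
        assert frac > 0.999

    def test_switch_errors_become_missing_never_wrong(self):
        cfg = SimulationConfig(n_samples=15, phase_switch_rate=0.01, seed=22)
        trio, truth = simulate_trio_haplotypes(cfg, 5000)
        calls = assign_parent_of_origin(trio)
        _, wrong = truth_assignment_check(trio, truth, calls)
        assert wrong == 0

    def test_assignment_monotone_in_switch_rate(self):
        fracs = []
        for rate in (0.05, 0.0):
            cfg = SimulationConfig(n_samples=10, phase_switch_rate=rate, seed=23)
            trio, truth = simulate_trio_haplotypes(cfg, 4000)
            calls = assign_parent_of_origin(trio)
            frac, _ = truth_assignment_check(trio, truth, calls)
            fracs.append(frac)
        assert fracs[1] >= fracs[0]

    def test_short_chromosome_falls_back_to_mendelian(self):
        cfg = SimulationConfig(n_samples=5, seed=24)
        trio, truth = simulate_trio_haplotypes(cfg, 40)  # < window size
        calls = assign_parent_of_origin(trio, window_size=100)
        assert set(calls["status"]).issubset({"mendelian", "missing"})
        _, wrong = truth_assignment_check(trio, truth, calls)
        assert wrong == 0

    def test_every_child_het_site_appears_exactly_once(self):
        cfg = SimulationConfig(n_samples=6, seed=25)
        trio, _ = simulate_trio_haplotypes(cfg, 1000)
        calls = assign_parent_of_origin(trio)
        het_total = int((trio.child[:, 0, :] != trio.child[:, 1, :]).sum())
        assert len(calls) == het_total
        assert not calls.duplicated(["chrom", "pos", "sample"]).any()
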