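import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from erap2hap.genotype_model import GenotypeTable, SNPDef
from erap2hap.haplotype_em import (
    em_from_joint_counts,
    em_from_pattern_counts,
    em_haplotype_freqs,
    ld_matrix,
    pairwise_ld,
    two_locus_counts,
)
from erap2hap.synthetic_cohort import preset, simulate_cohort

SNP_A = SNPDef("a", "G", "A")
SNP_B = SNPDef("b", "T", "G")


def coupling_fixed_point(counts: np.ndarray) -> dict[str, float]:
    """Independent oracle for the 2-locus EM on the published fetal table.

    With unambiguous haplotype tallies fixed by all single-het and
    double-hom cells, the EM fixed point reduces to one equation for the
    coupling mass m: the share of the double-heterozygote class resolved as
    the (minor_a-major_b, major_a-minor_b) pair, in proportion to the
    frequency products at the solution itself.
    """
    counts = np.asarray(counts, dtype=float)
    n_dh = counts[1, 1]
    # unambiguous haplotype counts (minor-dosage ascending indexing)
    tally = {"00": 0.0, "01": 0.0, "10": 0.0, "11": 0.0}
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = counts[i, j]
            haps = []
            a_alleles = ["1"] * i + ["0"] * (2 - i)
            b_alleles = ["1"] * j + ["0"] * (2 - j)
            if i == 1:
                haps = [("1" + b_alleles[0]), ("0" + b_alleles[1])]
            elif j == 1:
                haps = [(a_alleles[0] + "1"), (a_alleles[1] + "0")]
            else:
                haps = [a_alleles[0] + b_alleles[0]] * 2
            for h in haps:
                tally[h] += c
    two_n = 2 * counts.sum()

    def fp(m):
        f10 = tally["10"] + m
        f01 = tally["01"] + m
        f11 = tally["11"] + (n_dh - m)
        f00 = tally["00"] + (n_dh - m)
        return n_dh * (f10 * f01) / (f10 * f01 + f11 * f00) - m

    m = brentq(fp, 0.0, n_dh)
    return {
        "11": (tally["11"] + n_dh - m) / two_n,
        "10": (tally["10"] + m) / two_n,
        "01": (tally["01"] + m) / two_n,
        "00": (tally["00"] + n_dh - m) / two_n,
        "m": m,
    }


def grid_search_two_locus(counts: np.ndarray, step: float = 1e-4) -> float:
    """Brute-force maximizer of the 2-locus likelihood over the coupling
    haplotype frequency (margins fixed at observed allele frequencies).
    Returns the maximizing minor-minor haplotype frequency."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p_a = (counts.sum(axis=1) @ [0, 1, 2]) / (2 * n)
    p_b = (counts.sum(axis=0) @ [0, 1, 2]) / (2 * n)
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    best, best_ll = lo, -np.inf
    for p11 in np.arange(lo, hi + step / 2, step):
        h11, h10, h01 = p11, p_a - p11, p_b - p11
        h00 = 1 - p_a - p_b + p11
        cell = np.array(
            [
                [h00**2, 2 * h00 * h01, h01**2],
                [2 * h00 * h10, 2 * h11 * h00 + 2 * h10 * h01, 2 * h01 * h11],
                [h10**2, 2 * h10 * h11, h11**2],
            ]
        )
        ll = float((counts * np.log(np.maximum(cell, 1e-300))).sum())
        if ll > best_ll:
            best_ll, best = ll, p11
    return best


class TestEMPointEstimates:
    def test_uniform_homozygous_cohort_gives_single_haplotype(self):
        snps = [SNPDef("x", "A", "G"), SNPDef("y", "T", "C")]
        calls = np.zeros((10, 2), dtype=np.int8)  # all hom-major at both
        table = GenotypeTable([f"S{i}" for i in range(10)], snps, calls)
        dist = em_haplotype_freqs(table, ["x", "y"], seed=0)
        assert dist.freqs == {"AT": pytest.approx(1.0)}

    def test_published_fetal_pair_matches_fixed_point_oracle(
        self, chilean_pair_counts_minor, snp374, snp782
    ):
        oracle = coupling_fixed_point(chilean_pair_counts_minor)
        assert oracle["m"] == pytest.approx(25, abs=1)
        dist = em_from_joint_counts(
            chilean_pair_counts_minor, snp374, snp782, seed=0
        )
        # A = minor at rs2248374, G = minor at rs2549782
        assert dist.frequency_of("AG") == pytest.approx(oracle["11"], abs=1e-3)
        assert dist.frequency_of("AT") == pytest.approx(oracle["10"], abs=1e-3)
        assert dist.frequency_of("GG") == pytest.approx(oracle["01"], abs=1e-3)
        assert dist.frequency_of("GT") == pytest.approx(oracle["00"], abs=1e-3)
        # headline frequencies
        assert dist.frequency_of("AT") == pytest.approx(0.121, abs=2e-3)
        assert dist.frequency_of("AG") == pytest.approx(0.219, abs=2e-3)
        assert dist.frequency_of("GT") == pytest.approx(0.549, abs=2e-3)
        assert dist.frequency_of("GG") == pytest.approx(0.111, abs=2e-3)

    def test_five_snp_recovery_within_binomial_se(self):
        cfg = preset("african_american_5snp", n_samples=1100, missing_rate=0.0, seed=42)
        cohort = simulate_cohort(cfg)
        dist = em_haplotype_freqs(cohort.table, [s.id for s in cfg.snp_defs], seed=42)
        se = math.sqrt(0.436 * 0.564 / (2 * 1100))
        for hap, truth in zip(cfg.haplotypes, cfg.haplotype_freqs):
            assert abs(dist.frequency_of(hap) - truth) < 3 * se

    def test_no_complete_samples_errors(self):
        snps = [SNPDef("x", "A", "G"), SNPDef("y", "T", "C")]
        calls = np.array([[0, -1], [-1, 0]], dtype=np.int8)
        table = GenotypeTable(["S1", "S2"], snps, calls)
        with pytest.raises(ValueError, match="complete"):
            em_haplotype_freqs(table, ["x", "y"])


class TestEMProperties:
    def test_loglik_non_decreasing(self, chilean_pair_counts_minor, snp374, snp782):
        dist = em_from_joint_counts(chilean_pair_counts_minor, snp374, snp782, seed=0)
        path = np.array(dist.loglik_path)
        assert (np.diff(path) >= -1e-9).all()

    def test_margins_equal_observed_allele_frequencies(
        self, chilean_pair_counts_minor, snp374, snp782
    ):
        counts = chilean_pair_counts_minor
        n = counts.sum()
        p_a = (counts.sum(axis=1) @ [0, 1, 2]) / (2 * n)
        p_b = (counts.sum(axis=0) @ [0, 1, 2]) / (2 * n)
        dist = em_from_joint_counts(counts, snp374, snp782, seed=0)
        assert dist.minor_frequency(0) == pytest.approx(p_a, abs=1e-9)
        assert dist.minor_frequency(1) == pytest.approx(p_b, abs=1e-9)

    @given(cells=st.lists(st.integers(0, 10), min_size=9, max_size=9))
    @settings(max_examples=30, deadline=None)
    def test_two_locus_em_matches_grid_search(self, cells):
        counts = np.array(cells).reshape(3, 3)
        n = counts.sum()
        if n == 0 or n > 50:
            return
        dos_a = counts.sum(axis=1) @ [0, 1, 2]
        dos_b = counts.sum(axis=0) @ [0, 1, 2]
        if dos_a in (0, 2 * n) or dos_b in (0, 2 * n):
            return  # monomorphic: coupling frequency unidentifiable
        dist = em_from_joint_counts(counts, SNP_A, SNP_B, seed=1)
        p11_em = float(dist.freq_vector[0b11])
        p11_grid = grid_search_two_locus(counts)
        assert p11_em == pytest.approx(p11_grid, abs=1e-3)


class TestLDStats:
    def test_two_haplotype_system_perfect_ld(self):
        vec = np.zeros(4)
        vec[0b00] = 0.5
        vec[0b11] = 0.5
        from erap2hap.haplotype_em import HaplotypeDistribution

        dist = HaplotypeDistribution([SNP_A, SNP_B], vec, 0.0, 1, True, 100)
        ld = pairwise_ld(dist)
        assert ld.D_prime == pytest.approx(1.0)
        assert ld.r_squared == pytest.approx(1.0)

    def test_published_frequencies_two_haplotypes(self):
        vec = np.zeros(4)
        vec[0b11] = 0.436
        vec[0b00] = 0.564
        from erap2hap.haplotype_em import HaplotypeDistribution

        dist = HaplotypeDistribution([SNP_A, SNP_B], vec, 0.0, 1, True, 1100)
        ld = pairwise_ld(dist)
        assert ld.D_prime == pytest.approx(1.0)
        assert ld.r_squared == pytest.approx(1.0)

    def test_fetal_pair_ld_closed_forms(
        self, chilean_pair_counts_minor, snp374, snp782
    ):
        oracle = coupling_fixed_point(chilean_pair_counts_minor)
        p_a = oracle["11"] + oracle["10"]
        p_b = oracle["11"] + oracle["01"]
        d = oracle["11"] - p_a * p_b
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b) if d > 0 else min(
            p_a * p_b, (1 - p_a) * (1 - p_b)
        )
        dist = em_from_joint_counts(chilean_pair_counts_minor, snp374, snp782, seed=0)
        ld = pairwise_ld(dist)
        assert abs(ld.D) == pytest.approx(abs(d), abs=1e-3)
        assert ld.D_prime == pytest.approx(abs(d) / d_max, abs=1e-3)
        assert ld.D_prime == pytest.approx(0.49, abs=0.01)
        assert ld.r_squared == pytest.approx(0.23, abs=0.01)

    def test_monomorphic_pair_flagged(self):
        snps = [SNPDef("x", "A", "G"), SNPDef("y", "T", "C")]
        calls = np.array([[0, 0], [0, 1], [0, 2]], dtype=np.int8)
        table = GenotypeTable(["S1", "S2", "S3"], snps, calls)
        mat = ld_matrix(table)
        assert not mat.get(0, 1).defined

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_r2_bounded_by_dprime_squared(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(3, 3))
        n = counts.sum()
        dos_a = counts.sum(axis=1) @ [0, 1, 2]
        dos_b = counts.sum(axis=0) @ [0, 1, 2]
        if n == 0 or dos_a in (0, 2 * n) or dos_b in (0, 2 * n):
            return
        ld = pairwise_ld(em_from_joint_counts(counts, SNP_A, SNP_B, seed=seed))
        assert 0.0 <= ld.r_squared <= ld.D_prime**2 + 1e-9
        assert 0.0 <= ld.D_prime <= 1.0 + 1e-12

    def test_zero_haplotype_class_implies_dprime_one(self):
        vec = np.array([0.3, 0.2, 0.5, 0.0])  # one gamete absent
        from erap2hap.haplotype_em import HaplotypeDistribution

        dist = HaplotypeDistribution([SNP_A, SNP_B], vec, 0.0, 1, True, 50)
        assert pairwise_ld(dist).D_prime == pytest.approx(1.0, abs=1e-9)


class TestLDMatrix:
    def test_perfectly_linked_snps_all_r2_one(self):
        cfg = preset("african_american_5snp", n_samples=300, missing_rate=0.0, seed=9)
        table = simulate_cohort(cfg).table
        mat = ld_matrix(table, seed=9)
        r2 = mat.r2_matrix()
        off = r2[~np.isnan(r2)]
        assert off.size == 20
        assert np.allclose(off, 1.0)

    def test_matrix_is_symmetric(self):
        cfg = preset("chilean_4snp_plus_partial", n_samples=200, seed=5)
        table = simulate_cohort(cfg).table
        mat = ld_matrix(table, seed=5)
        dp = mat.dprime_matrix()
        assert np.allclose(dp, dp.T, equal_nan=True)

    def test_chilean_preset_partial_vs_block_dprime(self):
        cfg = preset("chilean_4snp_plus_partial", n_samples=1100, seed=13)
        table = simulate_cohort(cfg).table
        mat = ld_matrix(table, seed=13)
        dp = mat.dprime_matrix()
        # the 6 within-block pairs (indices 1..4) are in complete LD
        for i in range(1, 5):
            for j in range(i + 1, 5):
                assert dp[i, j] == pytest.approx(1.0, abs=0.02)
        # rs2549782 (index 0) shows intermediate D' with every block SNP
        for j in range(1, 5):
            assert 0.3 < dp[0, j] < 0.7

    def test_two_locus_counts_complete_cases(self, chilean_fetal_table):
        counts = two_locus_counts(chilean_fetal_table, "rs2248374", "rs2549782")
        assert counts.sum() == 1097
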