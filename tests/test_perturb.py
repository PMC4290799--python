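"""Task-1 release mechanisms: naive histogram and haplotype-block Laplace."""

import numpy as np
import pytest

from privgwas import (
    AlleleFrequencyTable,
    BlockHaplotypes,
    BlockMap,
    HaplotypeMatrix,
    HaplotypeTable,
    ParameterError,
    ValidationError,
    build_haplotype_table,
    common_haplotype_pool,
    haplotype_counts_to_allele_counts,
    map_rare_haplotypes,
    perturb_haplotype,
    perturb_naive,
)
from privgwas.mechanisms import allocate_budget
from privgwas.preprocess import compute_allele_counts

from conftest import random_haplotypes


def _counts(values, total=400.0):
    values = np.asarray(values, dtype=float)
    return AlleleFrequencyTable(
        [f"rs{i}" for i in range(len(values))], values, np.full(len(values), total)
    )


class TestPerturbNaive:
    def test_zero_noise_limit(self):
        t = _counts([10, 200, 395])
        out = perturb_naive(t, epsilon=1e12, seed=0)
        np.testing.assert_allclose(out.frequencies, t.frequencies, atol=1e-6)

    def test_noise_scale_is_2n_over_eps(self):
        # N = 10 SNVs, eps = 1 -> Laplace scale 20, variance 2*400 = 800
        t = _counts(np.full(10, 1e9), total=2e9)  # far from the clamp
        noise = np.concatenate(
            [perturb_naive(t, 1.0, seed=s).minor_counts - 1e9 for s in range(10_000)]
        )
        assert noise.var() == pytest.approx(800.0, rel=0.05)

    def test_clamped_to_valid_counts(self):
        t = _counts([1, 399])
        out = perturb_naive(t, epsilon=0.01, seed=3)
        assert (out.minor_counts >= 0).all() and (out.minor_counts <= 400).all()

    def test_round_flag_gives_integers(self):
        out = perturb_naive(_counts([100, 300]), 1.0, seed=1, round_counts=True)
        assert np.array_equal(out.minor_counts, np.round(out.minor_counts))

    def test_bad_epsilon(self):
        with pytest.raises(ParameterError):
            perturb_naive(_counts([1]), 0.0, seed=0)


def _two_snv_block_table():
    """2 individuals (4 copies), one block of 2 SNVs, copies {00,00,01,11}."""
    alleles = np.array([[0, 0], [0, 0], [0, 1], [1, 1]], dtype=np.int8)
    haps = HaplotypeMatrix(["I0", "I1"], ["rs0", "rs1"], alleles)
    blocks = BlockMap(blocks=[np.array([0, 1])], n_snvs=2)
    return haps, blocks


class TestBuildHaplotypeTable:
    def test_direct_tally(self):
        haps, blocks = _two_snv_block_table()
        t = build_haplotype_table(haps, blocks)
        entry = t.blocks[0]
        assert dict(zip(entry.haplotypes, entry.counts)) == {"00": 2, "01": 1, "11": 1}
        assert entry.total == 4

    def test_monomorphic_cohort(self):
        alleles = np.tile(np.array([[1, 0, 1]], dtype=np.int8), (6, 1))
        haps = HaplotypeMatrix([f"I{i}" for i in range(3)], ["a", "b", "c"], alleles)
        t = build_haplotype_table(haps, BlockMap([np.arange(3)], 3))
        assert t.blocks[0].haplotypes == ["101"]
        assert t.blocks[0].counts[0] == 6

    @pytest.mark.parametrize("seed", range(3))
    def test_totals_conserved(self, seed):
        haps = random_haplotypes(12, 7, seed=seed)
        blocks = BlockMap([np.arange(0, 5), np.arange(5, 12)], 12)
        t = build_haplotype_table(haps, blocks)
        assert all(e.counts.sum() == e.total == 14 for e in t.blocks)


class TestMapRareHaplotypes:
    def test_tie_goes_to_lowest_pool_index(self):
        table = HaplotypeTable([BlockHaplotypes(["011"], np.array([1.0]), 1.0)])
        out = map_rare_haplotypes(table, [["010", "111"]])
        # 011 is Hamming distance 1 from both pool members; lowest index wins
        assert dict(zip(out.blocks[0].haplotypes, out.blocks[0].counts)) == {
            "010": 1.0,
            "111": 0.0,
        }

    def test_in_pool_haplotypes_untouched(self):
        table = HaplotypeTable(
            [BlockHaplotypes(["00", "11"], np.array([3.0, 1.0]), 4.0)]
        )
        out = map_rare_haplotypes(table, [["00", "11"]])
        np.testing.assert_array_equal(out.blocks[0].counts, [3.0, 1.0])

    @pytest.mark.parametrize("seed", range(3))
    def test_totals_conserved(self, seed):
        haps = random_haplotypes(8, 9, seed=seed)
        blocks = BlockMap([np.arange(0, 4), np.arange(4, 8)], 8)
        t = build_haplotype_table(haps, blocks)
        pool = common_haplotype_pool(t, min_count=3)
        out = map_rare_haplotypes(t, pool)
        for before, after in zip(t.blocks, out.blocks):
            assert after.counts.sum() == pytest.approx(before.total)

    def test_empty_pool_rejected(self):
        table = HaplotypeTable([BlockHaplotypes(["0"], np.array([2.0]), 2.0)])
        with pytest.raises(ValidationError, match="pool"):
            map_rare_haplotypes(table, [[]])


class TestPerturbHaplotype:
    def _table(self):
        return HaplotypeTable(
            [
                BlockHaplotypes(["00", "01"], np.array([60.0, 40.0]), 100.0),
                BlockHaplotypes(["1", "0"], np.array([75.0, 25.0]), 100.0),
            ]
        )

    def test_zero_noise_limit(self):
        out = perturb_haplotype(self._table(), 1e12, seed=0)
        for before, after in zip(self._table().blocks, out.blocks):
            np.testing.assert_allclose(after.counts, before.counts, atol=1e-6)

    @pytest.mark.parametrize("eps", [0.1, 1.0])
    def test_totals_renormalized_exactly(self, eps):
        out = perturb_haplotype(self._table(), eps, seed=5)
        for entry in out.blocks:
            assert entry.counts.sum() == pytest.approx(entry.total, abs=1e-9)
            assert (entry.counts >= 0).all()

    def test_mean_preserves_counts(self):
        # 1 block, 2 haplotypes, n = 50 individuals: perturbation is unbiased
        # before clamping; measure the clamp-corrected mean over 5000 seeds
        base = HaplotypeTable([BlockHaplotypes(["0", "1"], np.array([70.0, 30.0]), 100.0)])
        sums = np.zeros(2)
        for s in range(5000):
            sums += perturb_haplotype(base, 1.0, seed=s).blocks[0].counts
        means = sums / 5000
        # Laplace scale 2/eps = 2, sd ~ 2.83 per count; renormalized pair
        se = 3 * 2.83 / np.sqrt(5000)
        assert abs(means[0] - 70.0) < 3 * se + 0.5  # clamp correction margin
        assert means.sum() == pytest.approx(100.0, abs=1e-6)

    def test_budget_allocation_proportional_to_pool(self):
        table = HaplotypeTable(
            [
                BlockHaplotypes(["00", "01", "10"], np.array([5.0, 3.0, 2.0]), 10.0),
                BlockHaplotypes(["0", "1"], np.array([6.0, 4.0]), 10.0),
            ]
        )
        eps = allocate_budget(table.pool_sizes(), 1.0)
        np.testing.assert_allclose(eps, [0.6, 0.4])
        assert eps.sum() == pytest.approx(1.0, abs=1e-12)


class TestDeriveAlleleCounts:
    def test_direct_sum_example(self):
        table = HaplotypeTable(
            [BlockHaplotypes(["00", "01", "11"], np.array([2.0, 1.0, 1.0]), 4.0)]
        )
        blocks = BlockMap([np.array([0, 1])], 2)
        out = haplotype_counts_to_allele_counts(table, blocks, ["rs0", "rs1"])
        assert out.minor_counts.tolist() == [1.0, 2.0]
        assert (out.totals == 4.0).all()

    def test_monomorphic_block_is_exact(self):
        table = HaplotypeTable([BlockHaplotypes(["10"], np.array([8.0]), 8.0)])
        out = haplotype_counts_to_allele_counts(
            table, BlockMap([np.array([0, 1])], 2), ["a", "b"]
        )
        assert out.frequencies.tolist() == [1.0, 0.0]

    @pytest.mark.parametrize("seed", range(4))
    def test_zero_noise_pipeline_matches_genotype_counts(self, seed):
        haps = random_haplotypes(14, 8, seed=seed)
        blocks = BlockMap([np.arange(0, 6), np.arange(6, 14)], 14)
        derived = haplotype_counts_to_allele_counts(
            build_haplotype_table(haps, blocks), blocks, haps.snv_ids
        )
        direct = compute_allele_counts(haps.collapse())
        np.testing.assert_array_equal(derived.minor_counts, direct.minor_counts)
        np.testing.assert_array_equal(derived.totals, direct.totals)


class TestDimensionalityReduction:
    def test_pool_sizes_are_an_order_smaller_than_snv_count(self, task1):
        pool = common_haplotype_pool(
            build_haplotype_table(task1.control_haps, task1.structure.block_map)
        )
        total_pool = sum(len(p) for p in pool)
        n = task1.case.n_snvs
        assert total_pool <= n / 5
        # and strictly fewer noise draws than the naive mechanism's N
        assert total_pool < n
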