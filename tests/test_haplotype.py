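"""EM haplotype frequencies, LD statistics, and block construction."""

import itertools

import numpy as np
import pytest

from pgxcombine import (
    BlockThresholds,
    HaplotypeFrequencyEM,
    SimulationConfig,
    VariantSpec,
    em_haplotype_freqs,
    gabriel_blocks,
    pairwise_ld,
    simulate_genotypes,
)
from pgxcombine.haplotype import _pair_classes


def _pool_config(pool, n, seed=7, k=None):
    k = k or len(pool[0][0])
    specs = [VariantSpec(f"rs{j}", "1", 1000 + j, "A", "G", 0.5) for j in range(k)]
    return SimulationConfig(
        n_subjects=n, seed=seed, variant_specs=specs, haplotype_pool=pool
    )


class TestEmHaplotypeFreqs:
    def test_all_hom_ref(self):
        G = np.zeros((20, 2), dtype=int)
        freqs = em_haplotype_freqs(G)
        assert freqs[(0, 0)] == pytest.approx(1.0)

    def test_matches_direct_counting_without_double_hets(self):
        """With no double heterozygote every subject's phase is known, so
        EM must equal direct haplotype counting."""
        G = np.array([[2, 2]] * 3 + [[0, 0]] * 4 + [[1, 0]] * 2 + [[0, 1]] * 1)
        freqs = em_haplotype_freqs(G)
        # hand count over 20 haplotypes:
        # 3x(1,1)+(1,1); 4x(0,0)+(0,0); 2x(1,0)+(0,0); 1x(0,1)+(0,0)
        assert freqs[(1, 1)] == pytest.approx(6 / 20)
        assert freqs[(0, 0)] == pytest.approx(11 / 20)
        assert freqs[(1, 0)] == pytest.approx(2 / 20)
        assert freqs[(0, 1)] == pytest.approx(1 / 20)

    def test_parameter_recovery_from_pool(self):
        pool = [((1, 1), 0.3), ((0, 0), 0.7)]
        matrix, _ = simulate_genotypes(_pool_config(pool, n=2000))
        freqs = em_haplotype_freqs(matrix.calls)
        assert freqs[(1, 1)] == pytest.approx(0.3, abs=0.03)
        assert freqs[(0, 0)] == pytest.approx(0.7, abs=0.03)

    def test_loglik_nondecreasing_and_freqs_sum_to_one(self, rng):
        for _ in range(5):
            G = rng.integers(0, 3, size=(60, 3))
            em = HaplotypeFrequencyEM().fit(G)
            assert em.haplotype_freqs_.sum() == pytest.approx(1.0, abs=1e-9)
            ll = em.log_likelihoods_
            assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))

    def test_three_locus_pool_recovery(self):
        pool = [((0, 0, 0), 0.5), ((1, 1, 0), 0.3), ((0, 1, 1), 0.2)]
        matrix, _ = simulate_genotypes(_pool_config(pool, n=3000))
        freqs = em_haplotype_freqs(matrix.calls)
        for hap, f in pool:
            assert freqs[hap] == pytest.approx(f, abs=0.03)


class TestPairwiseLd:
    def test_complete_ld(self):
        pool = [((1, 1), 0.3), ((0, 0), 0.7)]
        matrix, _ = simulate_genotypes(_pool_config(pool, n=500))
        ld = pairwise_ld(matrix.calls[:, 0], matrix.calls[:, 1])
        assert ld.dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)
        assert ld.dprime_ci[1] == pytest.approx(1.0)

    def test_independent_loci_have_negligible_r2(self):
        specs = [VariantSpec(f"rs{j}", "1", 1000 + j, "A", "G", 0.4) for j in range(2)]
        config = SimulationConfig(n_subjects=5000, seed=11, variant_specs=specs)
        matrix, _ = simulate_genotypes(config)
        ld = pairwise_ld(matrix.calls[:, 0], matrix.calls[:, 1])
        assert ld.r2 < 0.01

    def test_hand_counted_d_without_double_hets(self):
        """3 subjects, phase fully determined: D from hand-counted haplotypes."""
        ga = np.array([2, 0, 1])
        gb = np.array([2, 0, 0])
        # haplotypes: (1,1)x2, (0,0)x2, (1,0)+(0,0) -> pAB=2/6, pA=3/6, pB=2/6
        ld = pairwise_ld(ga, gb)
        assert ld.d == pytest.approx(2 / 6 - (3 / 6) * (2 / 6), abs=1e-6)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError):
            pairwise_ld(np.array([0, 0, 0]), np.array([0, 1, 2]))

    def test_r2_invariant_under_label_swap(self):
        pool = [((1, 1), 0.2), ((1, 0), 0.2), ((0, 0), 0.6)]
        matrix, _ = simulate_genotypes(_pool_config(pool, n=400))
        ga, gb = matrix.calls[:, 0], matrix.calls[:, 1]
        r2 = pairwise_ld(ga, gb).r2
        assert pairwise_ld(2 - ga, gb).r2 == pytest.approx(r2, abs=1e-6)
        assert pairwise_ld(ga, 2 - gb).r2 == pytest.approx(r2, abs=1e-6)

    def test_dprime_and_r2_in_unit_interval(self, rng):
        for _ in range(10):
            p = rng.uniform(0.1, 0.9, size=2)
            ga = rng.binomial(1, p[0], 300) + rng.binomial(1, p[0], 300)
            gb = rng.binomial(1, p[1], 300) + rng.binomial(1, p[1], 300)
            if len(set(ga)) == 1 or len(set(gb)) == 1:
                continue
            ld = pairwise_ld(ga, gb)
            assert 0.0 <= ld.dprime <= 1.0
            assert 0.0 <= ld.r2 <= 1.0
            assert ld.dprime_ci[0] <= ld.dprime_ci[1]


def _oracle_blocks(genotypes, thresholds):
    """Independent brute-force block finder: enumerate every contiguous
    span under the same pair rules, then the same greedy acceptance."""
    cls = _pair_classes(genotypes, thresholds)
    m = genotypes.shape[1]
    spans = []
    for i in range(m):
        for j in range(i + 1, m):
            pairs = [cls[a, b] for a, b in itertools.combinations(range(i, j + 1), 2)]
            informative = [p for p in pairs if p != 0]
            if informative and sum(p == 1 for p in informative) / len(informative) >= thresholds.informative_frac:
                spans.append((i, j))
    spans.sort(key=lambda s: (-(s[1] - s[0]), s[0]))
    used = set()
    accepted = []
    for i, j in spans:
        if not (set(range(i, j + 1)) & used):
            accepted.append((i, j))
            used |= set(range(i, j + 1))
    return sorted(accepted)


class TestGabrielBlocks:
    def test_two_variants_in_complete_ld_form_one_block(self):
        pool = [((1, 1), 0.3), ((0, 0), 0.7)]
        matrix, _ = simulate_genotypes(_pool_config(pool, n=500))
        blocks = gabriel_blocks(matrix.calls)
        assert len(blocks) == 1
        assert blocks[0].variant_indices == [0, 1]

    def test_six_variant_ancestral_block(self):
        """Six variants carried on two ancestral haplotypes form a single
        6-variant block (the two-haplotype structure seen in CYP2B6)."""
        pool = [((1,) * 6, 0.25), ((0,) * 6, 0.75)]
        matrix, _ = simulate_genotypes(_pool_config(pool, n=400))
        blocks = gabriel_blocks(matrix.calls)
        assert len(blocks) == 1
        assert blocks[0].n_variants == 6
        # the two ancestral haplotypes dominate the block's frequency mass
        top = sorted(blocks[0].haplotypes.values(), reverse=True)[:2]
        assert sum(top) > 0.99

    def test_two_blocks_separated_by_unlinked_variant(self):
        """Two independent 3-variant blocks with an unlinked variant between
        them: result equals the exhaustive span-enumeration oracle."""
        rng_a = _pool_config([((1, 1, 1), 0.4), ((0, 0, 0), 0.6)], n=500, seed=3)
        rng_b = _pool_config([((1, 1, 1), 0.3), ((0, 0, 0), 0.7)], n=500, seed=4)
        block_a, _ = simulate_genotypes(rng_a)
        block_b, _ = simulate_genotypes(rng_b)
        lone = SimulationConfig(
            n_subjects=500, seed=5,
            variant_specs=[VariantSpec("rsX", "1", 99, "A", "G", 0.5)],
        )
        lone_m, _ = simulate_genotypes(lone)
        G = np.column_stack([block_a.calls, lone_m.calls, block_b.calls])

        thr = BlockThresholds()
        blocks = gabriel_blocks(G, thresholds=thr)
        spans = [(b.variant_indices[0], b.variant_indices[-1]) for b in blocks]
        assert spans == _oracle_blocks(G, thr)
        assert spans == [(0, 2), (4, 6)]

    def test_matches_oracle_on_random_small_panels(self, rng):
        thr = BlockThresholds()
        for trial in range(3):
            pool = [((1, 1), 0.35), ((0, 0), 0.65)]
            pair, _ = simulate_genotypes(_pool_config(pool, n=300, seed=50 + trial))
            noise = rng.binomial(1, 0.5, (300, 3)) + rng.binomial(1, 0.5, (300, 3))
            G = np.column_stack([noise[:, :1], pair.calls, noise[:, 1:]])
            blocks = gabriel_blocks(G, thresholds=thr)
            spans = [(b.variant_indices[0], b.variant_indices[-1]) for b in blocks]
            assert spans == _oracle_blocks(G, thr)
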