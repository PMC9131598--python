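import numpy as np
import pytest

import msatpop as mp
from msatpop import popstats

from conftest import random_matrix
from oracles import (
    fis_components_oracle,
    hexp_pair_counting_oracle,
    richness_enumeration_oracle,
    wc_components_oracle,
)


def _gm(calls, pops):
    calls = np.asarray(calls)
    return mp.GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(calls.shape[0])],
        pop_labels=pops,
        loci=[f"L{l}" for l in range(calls.shape[1])],
        calls=calls,
    )


def _genotypes_to_gm(genos_by_pop, n_loci=1):
    """Stack per-pop (n, L, 2) arrays into one matrix."""
    calls = np.concatenate(genos_by_pop)
    pops = []
    for k, g in enumerate(genos_by_pop):
        pops += [f"P{k}"] * len(g)
    return _gm(calls, pops)


class TestHeterozygosity:
    def test_observed_extremes_and_fraction(self):
        gm = _gm([[[1, 2]], [[1, 3]], [[2, 3]], [[1, 1]], [[2, 2]]], ["P"] * 5)
        assert mp.observed_heterozygosity(gm, "P", 0) == 0.6
        gm_all_het = _gm([[[1, 2]], [[1, 3]]], ["P"] * 2)
        assert mp.observed_heterozygosity(gm_all_het, "P", 0) == 1.0
        gm_all_hom = _gm([[[1, 1]], [[2, 2]]], ["P"] * 2)
        assert mp.observed_heterozygosity(gm_all_hom, "P", 0) == 0.0

    def test_unbiased_expected_closed_form(self):
        # n=5 genotypes, allele counts {6, 4}: (10/9) * (1 - .36 - .16)
        gm = _gm([[[1, 1]], [[1, 1]], [[1, 2]], [[1, 2]], [[2, 2]]], ["P"] * 5)
        assert mp.unbiased_expected_heterozygosity(gm, "P", 0) == pytest.approx(
            (10 / 9) * (1 - 0.36 - 0.16)
        )

    def test_monomorphic_is_zero(self):
        gm = _gm([[[7, 7]], [[7, 7]]], ["P"] * 2)
        assert mp.unbiased_expected_heterozygosity(gm, "P", 0) == 0.0

    def test_equals_pair_counting_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            g = rng.integers(1, 5, size=(n, 1, 2))
            gm = _gm(g, ["P"] * n)
            assert mp.unbiased_expected_heterozygosity(gm, "P", 0) == pytest.approx(
                hexp_pair_counting_oracle(g[:, 0, :]), abs=1e-12
            )


class TestAllelicRichness:
    def test_full_sample_gives_observed_count(self):
        gm = _gm([[[1, 2]], [[3, 3]]], ["P"] * 2)
        assert mp.allelic_richness(gm, "P", 0, g=4) == pytest.approx(3.0)

    def test_three_a_one_b_g2(self):
        # copies {A,A,A,B}: all 6 pairs contain A, 3 contain B -> 1.5
        gm = _gm([[[1, 1]], [[1, 2]]], ["P"] * 2)
        assert mp.allelic_richness(gm, "P", 0, g=2) == pytest.approx(1.5)

    def test_monomorphic_is_one(self):
        gm = _gm([[[4, 4]], [[4, 4]]], ["P"] * 2)
        for g in (1, 2, 3, 4):
            assert mp.allelic_richness(gm, "P", 0, g=g) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 5))  # up to 8 gene copies
            geno = rng.integers(1, 4, size=(n, 1, 2))
            gm = _gm(geno, ["P"] * n)
            copies = geno[:, 0, :].ravel().tolist()
            for g in range(1, 2 * n + 1):
                assert mp.allelic_richness(gm, "P", 0, g=g) == pytest.approx(
                    richness_enumeration_oracle(copies, g), abs=1e-12
                )


class TestWeirCockerham:
    def test_fixed_difference_theta_one(self):
        gm = _gm(
            [[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]], ["A", "A", "B", "B"]
        )
        assert mp.pairwise_theta(gm, "A", "B") == pytest.approx(1.0)

    def test_monomorphic_locus_uninformative(self):
        gm = _gm([[[1, 1]], [[1, 1]]], ["A", "B"])
        assert mp.wc_components(gm, ["A", "B"], 0) is None

    def test_spec_toy_table_against_oracle(self):
        # pop1 {AA:2, Aa:2, aa:1}, pop2 {AA:1, Aa:1, aa:3}
        p1 = [[1, 1], [1, 1], [1, 2], [1, 2], [2, 2]]
        p2 = [[1, 1], [1, 2], [2, 2], [2, 2], [2, 2]]
        gm = _genotypes_to_gm([np.array(p1)[:, None, :], np.array(p2)[:, None, :]])
        abc = mp.wc_components(gm, ["P0", "P1"], 0)
        oracle = wc_components_oracle([p1, p2])
        assert abc == pytest.approx(oracle, abs=1e-12)

    def test_random_tables_match_oracle_to_1e12(self, rng):
        for _ in range(50):
            r = int(rng.integers(2, 5))
            genos = [
                rng.integers(1, 5, size=(int(rng.integers(2, 21)), 1, 2))
                for _ in range(r)
            ]
            gm = _genotypes_to_gm(genos)
            pops = gm.populations
            abc = mp.wc_components(gm, pops, 0)
            if abc is None:
                continue
            oracle = wc_components_oracle([g[:, 0, :] for g in genos])
            assert abc == pytest.approx(oracle, abs=1e-12)

    def test_multilocus_fis_extremes(self):
        no_het = _gm([[[1, 1]], [[2, 2]], [[1, 1]]], ["P"] * 3)
        assert mp.multilocus_fis(no_het, "P") == pytest.approx(1.0)
        all_het = _gm([[[1, 2]], [[1, 2]], [[1, 2]]], ["P"] * 3)
        assert mp.multilocus_fis(all_het, "P") < 0

    def test_fis_matches_oracle_on_random_tables(self, rng):
        for _ in range(50):
            g = rng.integers(1, 4, size=(int(rng.integers(2, 15)), 2, 2))
            gm = _gm(g, ["P"] * g.shape[0])
            f = mp.multilocus_fis(gm, "P")
            B = C = 0.0
            for l in range(2):
                al = np.unique(g[:, l, :])
                if al.size < 2:
                    continue
                b, c = fis_components_oracle(g[:, l, :])
                B += b
                C += c
            if B + C == 0:
                assert np.isnan(f)
            else:
                assert f == pytest.approx(1 - C / (B + C), abs=1e-12)

    def test_locus_order_and_uninformative_drop_invariance(self, rng):
        gm = random_matrix(rng, n_pops=2, n_per_pop=8, n_loci=4)
        t0 = mp.pairwise_theta(gm, "Pop1", "Pop2")
        perm = [2, 0, 3, 1]
        gm2 = mp.GenotypeMatrix(
            gm.sample_ids, gm.pop_labels,
            [gm.loci[i] for i in perm], gm.calls[:, perm],
        )
        assert mp.pairwise_theta(gm2, "Pop1", "Pop2") == pytest.approx(t0)
        # appending a monomorphic locus changes nothing
        mono = np.full((gm.n_samples, 1, 2), 9, dtype=np.int32)
        gm3 = mp.GenotypeMatrix(
            gm.sample_ids, gm.pop_labels, gm.loci + ["M"],
            np.concatenate([gm.calls, mono], axis=1),
        )
        assert mp.pairwise_theta(gm3, "Pop1", "Pop2") == pytest.approx(t0)

    def test_theta_near_zero_for_split_panmictic_pool(self, rng):
        vals = []
        for _ in range(20):
            calls = rng.integers(1, 8, size=(100, 5, 2)).astype(np.int32)
            gm = _gm(calls, ["A"] * 50 + ["B"] * 50)
            vals.append(mp.pairwise_theta(gm, "A", "B"))
        assert abs(np.mean(vals)) < 0.01


class TestPermutationTest:
    def test_seed_determinism(self, rng):
        gm = random_matrix(rng, n_pops=2, n_per_pop=10, n_loci=3)
        r1 = mp.permutation_test(gm, "theta", B=200, seed=5, pops=("Pop1", "Pop2"))
        r2 = mp.permutation_test(gm, "theta", B=200, seed=5, pops=("Pop1", "Pop2"))
        assert r1 == r2

    def test_extreme_observed_gives_min_pvalue(self):
        # fixed difference: no permutation can reach the observed theta = 1
        calls = np.array([[[1, 1]]] * 6 + [[[2, 2]]] * 6)
        gm = _gm(calls, ["A"] * 6 + ["B"] * 6)
        theta, p = mp.permutation_test(gm, "theta", B=99, seed=1, pops=("A", "B"))
        assert theta == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_fis_permutation_flags_heterozygote_deficit(self, rng):
        # two alleles, all homozygotes: maximal deficit
        calls = np.array([[[1, 1]]] * 10 + [[[2, 2]]] * 10)
        gm = _gm(calls, ["P"] * 20)
        f, p = mp.permutation_test(gm, "fis", B=199, seed=3, pop="P")
        assert f == pytest.approx(1.0)
        assert p < 0.05

    def test_vectorized_theta_perms_match_scalar_recomputation(self, rng):
        """The batched permutation statistics equal pairwise_theta applied to
        explicitly relabeled matrices."""
        gm = random_matrix(rng, n_pops=2, n_per_pop=8, n_loci=3, missing_rate=0.1)
        gen = np.random.default_rng(77)
        perms = popstats._theta_perm_stats(gm, "Pop1", "Pop2", B=5, rng=gen)
        gen2 = np.random.default_rng(77)
        idx = np.flatnonzero(
            gm.pop_mask("Pop1") | gm.pop_mask("Pop2")
        )
        n = idx.size
        n_a = int(gm.pop_mask("Pop1").sum())
        ranks = gen2.random((5, n)).argsort(axis=1).argsort(axis=1)
        for b in range(5):
            labels = ["Pop1" if r < n_a else "Pop2" for r in ranks[b]]
            gm_b = mp.GenotypeMatrix(
                [gm.sample_ids[i] for i in idx], labels, gm.loci, gm.calls[idx]
            )
            assert perms[b] == pytest.approx(
                mp.pairwise_theta(gm_b, "Pop1", "Pop2"), abs=1e-10
            )


class TestAdjustedLevel:
    def test_sixty_six_pairwise_tests(self):
        assert mp.adjusted_nominal_level(0.05, 66) == pytest.approx(
            0.000758, abs=5e-7
        )

    def test_single_test_identity(self):
        assert mp.adjusted_nominal_level(0.05, 1) == 0.05

    def test_twenty_two_tests(self):
        assert mp.adjusted_nominal_level(0.05, 22) == pytest.approx(0.0023, abs=5e-5)


class TestTables:
    def test_diversity_table_shape_and_ranges(self, small_bundle):
        gm = small_bundle.clean
        df = mp.diversity_table(gm, B=100, seed=1)
        assert list(df["pop"]) == gm.populations
        assert ((df["H_exp"] >= 0) & (df["H_exp"] <= 1)).all()
        assert ((df["H_obs"] >= 0) & (df["H_obs"] <= 1)).all()
        assert (df["allelic_richness"] >= 1).all()
        assert df["F_is"].abs().max() <= 1
        assert (df["N"].sum()) == gm.n_samples

    def test_fst_matrix_symmetry_and_mask(self, small_bundle):
        gm = small_bundle.clean
        fm = mp.fst_matrix(gm, B=50, seed=2)
        k = len(gm.populations)
        assert fm.theta.shape == (k, k)
        assert np.allclose(fm.theta.values, fm.theta.values.T)
        assert np.allclose(np.diag(fm.theta.values), 0)
        assert fm.alpha_adjusted == pytest.approx(0.05 / (k * (k - 1) / 2))
        sig = fm.significant
        assert ((fm.pvalues.values < fm.alpha_adjusted)[~np.eye(k, dtype=bool)]
                == sig.values[~np.eye(k, dtype=bool)]).all()
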