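import itertools

import numpy as np
import pytest

from msatld.genodata import GenotypeDataset, Population, ValidationError
from msatld.popstruct import (
    UndefinedStatistic,
    amova,
    fst_permutation_test,
    pairwise_fst,
    relatedness_qg,
)
from conftest import random_dataset


def two_pop_dataset(geno_a, geno_b, names=("pA", "pB")):
    ga = np.asarray(geno_a, dtype=np.int32)
    gb = np.asarray(geno_b, dtype=np.int32)
    n_loci = ga.shape[1]
    return GenotypeDataset(
        [f"L{i:02d}" for i in range(n_loci)],
        [
            Population(names[0], "marine", False, ga, []),
            Population(names[1], "pond", False, gb, []),
        ],
    )


class TestFst:
    def test_fixed_differences_give_theta_one(self):
        ga = np.full((8, 3, 2), 100, dtype=np.int32)
        gb = np.full((8, 3, 2), 104, dtype=np.int32)
        ds = two_pop_dataset(ga, gb)
        assert pairwise_fst(ds, "pA", "pB") == pytest.approx(1.0)

    def test_panmictic_samples_near_zero(self):
        rng = np.random.default_rng(0)
        pool = np.array([100, 104, 108, 112], dtype=np.int32)
        p = np.array([0.4, 0.3, 0.2, 0.1])
        ga = pool[rng.choice(4, size=(200, 8, 2), p=p)]
        gb = pool[rng.choice(4, size=(200, 8, 2), p=p)]
        ds = two_pop_dataset(ga, gb)
        assert abs(pairwise_fst(ds, "pA", "pB")) < 0.02

    def test_invariant_to_allele_relabeling(self):
        ds = random_dataset(5, n_pops=2, n_ind=10, n_loci=4, missing_rate=0.1)
        theta = pairwise_fst(ds, "pop0", "pop1")
        relabel = {0: 0, 104: 992, 108: 104, 112: 108, 116: 116}
        for pop in ds.populations:
            g = pop.genotypes
            pop.genotypes = np.vectorize(lambda a: relabel.get(int(a), int(a)))(g).astype(np.int32)
        assert pairwise_fst(ds, "pop0", "pop1") == pytest.approx(theta, abs=1e-12)

    def test_no_shared_polymorphic_locus_flagged(self):
        ga = np.full((5, 2, 2), 100, dtype=np.int32)
        gb = np.full((5, 2, 2), 100, dtype=np.int32)
        ds = two_pop_dataset(ga, gb)
        with pytest.raises(UndefinedStatistic):
            pairwise_fst(ds, "pA", "pB")

    def test_permutation_p_attains_lower_bound(self):
        # fully fixed differences: no permutation reaches theta = 1
        ga = np.full((10, 4, 2), 100, dtype=np.int32)
        gb = np.full((10, 4, 2), 104, dtype=np.int32)
        ds = two_pop_dataset(ga, gb)
        theta, p = fst_permutation_test(ds, "pA", "pB", n_perm=199, seed=3)
        assert theta == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(1)
        pool = np.array([100, 104], dtype=np.int32)
        ga = pool[rng.integers(0, 2, size=(30, 5, 2))]
        gb = pool[rng.integers(0, 2, size=(30, 5, 2))]
        ds = two_pop_dataset(ga, gb)
        _, p = fst_permutation_test(ds, "pA", "pB", n_perm=199, seed=4)
        assert 0 < p <= 1


def oracle_amova(pop_copies, group_of):
    """Hand SSD decomposition on gene copies with 0/1 allele distance.

    pop_copies: per population a list of allele codes (one locus).
    Returns (sigma_a, sigma_b, sigma_c) via explicit pairwise distances.
    """
    def ssd(groups):
        total = 0.0
        for g in groups:
            n = len(g)
            if n == 0:
                continue
            s = sum(
                1.0 for x, y in itertools.combinations(g, 2) if x != y
            )
            total += s / n
        return total

    all_copies = [c for pop in pop_copies for c in pop]
    N = len(all_copies)
    P = len(pop_copies)
    G = len(set(group_of))
    groups = {}
    for i, g in enumerate(group_of):
        groups.setdefault(g, []).extend(pop_copies[i])

    ssd_t = ssd([all_copies])
    ssd_wp = ssd(pop_copies)
    ssd_wg = ssd(list(groups.values()))
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_t - ssd_wg

    sizes = np.array([len(p) for p in pop_copies], dtype=float)
    gsizes = {g: sum(len(pop_copies[i]) for i, gg in enumerate(group_of) if gg == g)
              for g in groups}
    sigma_c = ssd_wp / (N - P)
    sum_sq_over_group = sum(
        sum(sizes[i] ** 2 for i, gg in enumerate(group_of) if gg == g) / gsizes[g]
        for g in groups
    )
    n1 = (N - sum_sq_over_group) / (P - G)
    sigma_b = (ssd_ap / (P - G) - sigma_c) / n1
    if G > 1:
        n2 = (sum_sq_over_group - (sizes**2).sum() / N) / (G - 1)
        n3 = (N - sum(gs**2 for gs in gsizes.values()) / N) / (G - 1)
        sigma_a = (ssd_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c


class TestAmova:
    def _toy(self):
        # 3 populations x 4 diploids x 2 loci
        rng = np.random.default_rng(12)
        pool = np.array([100, 104, 108], dtype=np.int32)
        pops = []
        probs = [(0.7, 0.2, 0.1), (0.2, 0.6, 0.2), (0.1, 0.2, 0.7)]
        for i, p in enumerate(probs):
            geno = pool[rng.choice(3, size=(4, 2, 2), p=p)]
            pops.append(
                Population(f"p{i}", ["marine", "lake", "pond"][i], False, geno, [])
            )
        return GenotypeDataset(["L00", "L01"], pops)

    def test_matches_hand_ssd_decomposition(self):
        ds = self._toy()
        grouping = {"p0": "g1", "p1": "g1", "p2": "g2"}
        res = amova(ds, grouping)
        group_of = [0, 0, 1]
        exp = np.zeros(3)
        for l in range(2):
            copies = [pop.genotypes[:, l, :].ravel().tolist() for pop in ds.populations]
            exp += np.array(oracle_amova(copies, group_of))
        assert res.sigma_a == pytest.approx(exp[0], abs=1e-10)
        assert res.sigma_b == pytest.approx(exp[1], abs=1e-10)
        assert res.sigma_c == pytest.approx(exp[2], abs=1e-10)
        assert res.percent_a + res.percent_b + res.percent_c == pytest.approx(100.0)

    def test_single_group_splits_into_two_components(self):
        ds = self._toy()
        res = amova(ds, {"p0": "g", "p1": "g", "p2": "g"})
        assert res.sigma_a == 0.0
        assert res.percent_b + res.percent_c == pytest.approx(100.0)

    def test_fixed_differences_within_group_leave_no_within_variance(self):
        ga = np.full((6, 2, 2), 100, dtype=np.int32)
        gb = np.full((6, 2, 2), 104, dtype=np.int32)
        ds = two_pop_dataset(ga, gb)
        res = amova(ds, {"pA": "g", "pB": "g"})
        assert res.percent_c == pytest.approx(0.0, abs=1e-9)

    def test_each_population_its_own_group_zeroes_within_group_component(self):
        ds = self._toy()
        res = amova(ds, {"p0": "a", "p1": "b", "p2": "c"})
        assert res.sigma_b == pytest.approx(0.0, abs=1e-12)

    def test_unknown_population_rejected(self):
        ds = self._toy()
        with pytest.raises(ValidationError):
            amova(ds, {"p0": "a", "p1": "b", "p2": "c", "ghost": "a"})

    def test_permutation_p_values_reported(self):
        ds = self._toy()
        res = amova(ds, {"p0": "g1", "p1": "g1", "p2": "g2"}, n_perm=49, seed=0)
        for p in (res.p_a, res.p_b, res.p_c):
            assert 0 < p <= 1


class TestRelatednessQG:
    def test_duplicated_individual_close_to_one(self):
        rng = np.random.default_rng(3)
        n_loci = 60
        pool = np.array([100, 104, 108, 112, 116, 120], dtype=np.int32)
        base = pool[rng.integers(0, 6, size=(10, n_loci, 2))]
        geno = np.concatenate([base, base[:1]], axis=0)  # last is a copy of first
        ds = GenotypeDataset(
            [f"L{i:02d}" for i in range(n_loci)],
            [Population("p1", "lake", False, geno, [])],
        )
        r = relatedness_qg(ds, "p1").to_numpy()
        assert r[0, -1] > 0.9

    def test_unrelated_individuals_near_zero(self):
        rng = np.random.default_rng(4)
        n_loci = 80
        pool = np.array([100, 104, 108, 112], dtype=np.int32)
        geno = pool[rng.integers(0, 4, size=(20, n_loci, 2))]
        ds = GenotypeDataset(
            [f"L{i:02d}" for i in range(n_loci)],
            [Population("p1", "lake", False, geno, [])],
        )
        r = relatedness_qg(ds, "p1").to_numpy()
        off = r[np.triu_indices(20, 1)]
        assert abs(np.nanmean(off)) < 0.05
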