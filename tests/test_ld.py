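import itertools

import numpy as np
import pandas as pd
import pytest

from msatld.genodata import MarkerMap
from msatld.ld import (
    MonomorphicLocusError,
    bin_ld_by_distance,
    composite_delta,
    composite_ld,
    dprime_multiallelic,
    em_haplotype_frequencies,
    fit_ld_decay,
    haplotype_table_from_freqs,
    ld_measure_correlation,
    r2_multiallelic,
    syntenic_ld_scan,
)
from conftest import dataset_from_genotypes, random_dataset


# ---------------------------------------------------------------------------
# independent term-by-term oracles (plain python loops)
# ---------------------------------------------------------------------------

def oracle_dprime(freq):
    freq = np.asarray(freq, dtype=float)
    pa = freq.sum(axis=1)
    pb = freq.sum(axis=0)
    total = 0.0
    for i in range(freq.shape[0]):
        for j in range(freq.shape[1]):
            d = freq[i, j] - pa[i] * pb[j]
            if d < 0:
                dmax = min(pa[i] * pb[j], (1 - pa[i]) * (1 - pb[j]))
            else:
                dmax = min(pa[i] * (1 - pb[j]), pb[j] * (1 - pa[i]))
            if dmax > 0:
                total += pa[i] * pb[j] * abs(d / dmax)
    return total


def oracle_r2(freq):
    freq = np.asarray(freq, dtype=float)
    pa = freq.sum(axis=1)
    pb = freq.sum(axis=0)
    total = 0.0
    for i in range(freq.shape[0]):
        for j in range(freq.shape[1]):
            denom = pa[i] * (1 - pa[i]) * pb[j] * (1 - pb[j])
            if denom > 0:
                d = freq[i, j] - pa[i] * pb[j]
                total += pa[i] * pb[j] * d * d / denom
    return total


def random_joint_table(rng, k, l):
    freq = rng.dirichlet(np.ones(k * l)).reshape(k, l)
    return haplotype_table_from_freqs(freq)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

class TestEM:
    def test_unambiguous_double_homozygotes(self):
        geno = [[[100, 100], [200, 200]]] * 3 + [[[104, 104], [204, 204]]] * 3
        ds = dataset_from_genotypes(np.array(geno))
        h = em_haplotype_frequencies(ds, "p1", "L00", "L01")
        assert h.source == "direct"
        idx_a = {a: i for i, a in enumerate(h.alleles_a.tolist())}
        idx_b = {b: i for i, b in enumerate(h.alleles_b.tolist())}
        assert h.freq[idx_a[100], idx_b[200]] == pytest.approx(0.5)
        assert h.freq[idx_a[104], idx_b[204]] == pytest.approx(0.5)
        assert h.freq.sum() == pytest.approx(1.0)

    def test_single_double_heterozygote_fixed_point(self):
        ds = dataset_from_genotypes(np.array([[[100, 104], [200, 204]]]))
        h = em_haplotype_frequencies(ds, "p1", "L00", "L01")
        assert np.allclose(h.freq, 0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_margins_equal_observed_frequencies(self, seed):
        ds = random_dataset(seed, n_pops=1, n_ind=30, n_loci=2, missing_rate=0.1)
        h = em_haplotype_frequencies(ds, "pop0", "L00", "L01")
        pop = ds.populations[0]
        g = pop.genotypes
        ok = (g[:, 0, :] != 0).all(1) & (g[:, 1, :] != 0).all(1)
        for axis, (alleles, margin) in enumerate(
            [(h.alleles_a, h.margin_a), (h.alleles_b, h.margin_b)]
        ):
            copies = g[ok, axis, :].ravel()
            for a, m in zip(alleles, margin):
                assert m == pytest.approx(np.mean(copies == a), abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_monotone(self, seed):
        ds = random_dataset(seed, n_pops=1, n_ind=30, n_loci=2, missing_rate=0.0)
        h = em_haplotype_frequencies(ds, "pop0", "L00", "L01")
        ll = h.loglik_history
        assert np.all(np.diff(ll) >= -1e-10)

    def test_recovers_known_haplotype_frequencies(self):
        rng = np.random.default_rng(11)
        freqs = {(100, 200): 0.4, (100, 204): 0.1, (104, 200): 0.1, (104, 204): 0.4}
        haps = list(freqs)
        n = 500
        draws = rng.choice(len(haps), size=2 * n, p=list(freqs.values()))
        geno = np.empty((n, 2, 2), dtype=np.int32)
        for i in range(n):
            h1, h2 = haps[draws[2 * i]], haps[draws[2 * i + 1]]
            geno[i, 0] = (h1[0], h2[0])
            geno[i, 1] = (h1[1], h2[1])
        ds = dataset_from_genotypes(geno)
        h = em_haplotype_frequencies(ds, "p1", "L00", "L01")
        se = 3 * np.sqrt(0.4 * 0.6 / (2 * n))
        for (a, b), f in freqs.items():
            ia = h.alleles_a.tolist().index(a)
            ib = h.alleles_b.tolist().index(b)
            assert abs(h.freq[ia, ib] - f) < se


# ---------------------------------------------------------------------------
# D' and r^2
# ---------------------------------------------------------------------------

class TestDprimeR2:
    def test_complete_association_biallelic(self):
        h = haplotype_table_from_freqs([[0.5, 0.0], [0.0, 0.5]])
        assert dprime_multiallelic(h) == pytest.approx(1.0)

    def test_independent_loci_zero(self):
        pa = np.array([0.5, 0.3, 0.2])
        pb = np.array([0.6, 0.4])
        h = haplotype_table_from_freqs(np.outer(pa, pb))
        assert dprime_multiallelic(h) == pytest.approx(0.0, abs=1e-12)
        assert r2_multiallelic(h) == pytest.approx(0.0, abs=1e-12)

    def test_classical_biallelic_r2(self):
        # D = 0.4 - 0.25 = 0.15; r2 = 0.0225/0.0625 = 0.36
        h = haplotype_table_from_freqs([[0.4, 0.1], [0.1, 0.4]])
        assert r2_multiallelic(h) == pytest.approx(0.36)
        d, dmax = 0.15, min(0.5 * 0.5, 0.5 * 0.5)
        assert dprime_multiallelic(h) == pytest.approx(abs(d / dmax))

    @pytest.mark.parametrize("shape", [(2, 2), (3, 2), (3, 3), (5, 4)])
    def test_matches_term_by_term_oracle(self, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        for _ in range(50):
            h = random_joint_table(rng, *shape)
            assert dprime_multiallelic(h) == pytest.approx(
                oracle_dprime(h.freq), abs=1e-12
            )
            assert r2_multiallelic(h) == pytest.approx(oracle_r2(h.freq), abs=1e-12)

    def test_dprime_bounded_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k, l = rng.integers(2, 6, size=2)
            h = random_joint_table(rng, k, l)
            dp = dprime_multiallelic(h)
            assert 0.0 <= dp <= 1.0 + 1e-12
            assert r2_multiallelic(h) >= 0.0

    def test_monomorphic_locus_rejected(self):
        h = haplotype_table_from_freqs([[0.6, 0.4]])
        with pytest.raises(MonomorphicLocusError):
            dprime_multiallelic(h)


# ---------------------------------------------------------------------------
# Composite LD
# ---------------------------------------------------------------------------

class TestComposite:
    def test_complete_association_double_homozygotes(self):
        geno = [[[100, 100], [200, 200]]] * 5 + [[[104, 104], [204, 204]]] * 5
        ds = dataset_from_genotypes(np.array(geno))
        cdp, cr2 = composite_ld(ds, "p1", "L00", "L01")
        assert cdp == pytest.approx(1.0)
        assert cr2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_haplotypic_without_double_heterozygotes(self, seed):
        # locus B always homozygous -> phase never ambiguous
        rng = np.random.default_rng(seed)
        n = 40
        ga = rng.choice([100, 104, 108], size=(n, 2)).astype(np.int32)
        hb = rng.choice([200, 204, 208], size=n)
        gb = np.stack([hb, hb], axis=1).astype(np.int32)
        geno = np.stack([ga, gb], axis=1)
        ds = dataset_from_genotypes(geno)
        h = em_haplotype_frequencies(ds, "p1", "L00", "L01")
        assert h.source == "direct"
        _, _, pa, pb, d_comp = composite_delta(ga, gb)
        d_hap = h.freq - np.outer(h.margin_a, h.margin_b)
        assert np.allclose(d_comp, d_hap, atol=1e-12)

    def test_random_union_of_gametes_near_zero(self):
        rng = np.random.default_rng(5)
        n = 1000
        ha = rng.choice([100, 104], size=(n, 2))
        hb = rng.choice([200, 204], size=(n, 2))
        geno = np.stack([ha, hb], axis=1).astype(np.int32)
        ds = dataset_from_genotypes(geno)
        cdp, cr2 = composite_ld(ds, "p1", "L00", "L01")
        # 3 SE scale for the biallelic composite correlation at n=1000
        assert cr2 < 9.0 / n * 2
        assert cdp < 0.15


# ---------------------------------------------------------------------------
# Scans, bins, decay, correlation
# ---------------------------------------------------------------------------

def toy_map(rows):
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "lg", "position_mb"]))


class TestScan:
    def _dataset(self, n_loci, seed=0, n_ind=20):
        return random_dataset(seed, n_pops=1, n_ind=n_ind, n_loci=n_loci,
                              missing_rate=0.0, n_alleles=3)

    def test_pair_count_from_lg_sizes(self):
        ds = self._dataset(5)
        mm = toy_map(
            [("L00", 1, 0.0), ("L01", 1, 1.0), ("L02", 1, 2.0),
             ("L03", 2, 0.0), ("L04", 2, 1.5)]
        )
        rec = syntenic_ld_scan(ds, mm, "pop0")
        assert len(rec) == 4

    def test_monomorphic_locus_pairs_omitted(self):
        ds = self._dataset(3, seed=1)
        ds.populations[0].genotypes[:, 1, :] = 100  # make L01 monomorphic
        mm = toy_map([("L00", 1, 0.0), ("L01", 1, 1.0), ("L02", 1, 2.0)])
        rec = syntenic_ld_scan(ds, mm, "pop0")
        assert len(rec) == 1
        assert {rec.locusA[0], rec.locusB[0]} == {"L00", "L02"}

    def test_distinct_lgs_give_no_records(self):
        ds = self._dataset(3)
        mm = toy_map([("L00", 1, 0.0), ("L01", 2, 1.0), ("L02", 3, 2.0)])
        rec = syntenic_ld_scan(ds, mm, "pop0")
        assert rec.empty

    def test_exclude_rare_never_increases_allele_counts(self):
        ds = random_dataset(9, n_pops=1, n_ind=30, n_loci=4, n_alleles=6,
                            missing_rate=0.0)
        mm = toy_map([(f"L0{i}", 1, float(i)) for i in range(4)])
        full = syntenic_ld_scan(ds, mm, "pop0", exclude_rare=False)
        reduced = syntenic_ld_scan(ds, mm, "pop0", exclude_rare=True)
        merged = full.merge(reduced, on=["locusA", "locusB"], suffixes=("", "_r"))
        assert (merged.n_alleles_A_r <= merged.n_alleles_A).all()
        assert (merged.n_alleles_B_r <= merged.n_alleles_B).all()


class TestBins:
    def test_single_pair(self):
        rec = pd.DataFrame({"distance_mb": [2.0], "dprime": [0.6]})
        out = bin_ld_by_distance(rec)
        row = out[out.bin == "0-5 Mb"].iloc[0]
        assert row["mean"] == pytest.approx(0.6)
        assert row["error"] == 0.0
        assert row["n_pairs"] == 1

    def test_two_bins_and_overall(self):
        rec = pd.DataFrame({"distance_mb": [0.5, 7.0], "dprime": [0.4, 0.8]})
        out = bin_ld_by_distance(rec).set_index("bin")
        assert out.loc["0-5 Mb", "mean"] == pytest.approx(0.4)
        assert out.loc["5.001-10 Mb", "mean"] == pytest.approx(0.8)
        assert out.loc["overall", "mean"] == pytest.approx(0.6)

    def test_right_closed_edges(self):
        rec = pd.DataFrame({"distance_mb": [5.0, 5.001, 20.0, 20.5],
                            "dprime": [1, 2, 3, 4.0]})
        out = bin_ld_by_distance(rec).set_index("bin")
        assert out.loc["0-5 Mb", "n_pairs"] == 1
        assert out.loc["5.001-10 Mb", "n_pairs"] == 1
        assert out.loc["15.001-20 Mb", "n_pairs"] == 1
        assert out.loc[">20 Mb", "n_pairs"] == 1

    def test_error_is_sd_over_sqrt_n(self):
        rng = np.random.default_rng(2)
        vals = rng.random(10)
        rec = pd.DataFrame({"distance_mb": np.full(10, 1.0), "dprime": vals})
        out = bin_ld_by_distance(rec).set_index("bin")
        expected = vals.std(ddof=1) / np.sqrt(10)
        assert out.loc["0-5 Mb", "error"] == pytest.approx(expected)
        # overall mean is the pair-weighted mean of all records
        assert out.loc["overall", "mean"] == pytest.approx(vals.mean())


class TestDecay:
    def test_exact_logarithmic_curve(self):
        d = np.array([0.5, 1, 2, 5, 10, 20, 40.0])
        rec = pd.DataFrame({"distance_mb": d, "dprime": 0.9 - 0.1 * np.log(d)})
        fit = fit_ld_decay(rec)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-0.1)
        assert fit.half_length_mb == pytest.approx(np.exp(4.0))

    def test_constant_dprime(self):
        rec = pd.DataFrame({"distance_mb": [1, 2, 4.0], "dprime": [0.6] * 3})
        fit = fit_ld_decay(rec)
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0
        assert fit.half_length_mb is None

    def test_positive_slope_has_no_half_length(self):
        d = np.array([1, 2, 4, 8.0])
        rec = pd.DataFrame({"distance_mb": d, "dprime": 0.2 + 0.05 * np.log(d)})
        fit = fit_ld_decay(rec)
        assert fit.half_length_mb is None


class TestMeasureCorrelation:
    def test_perfect_agreement(self):
        rec = pd.DataFrame({"dprime": [0.1, 0.4, 0.8], "r2": [0.1, 0.4, 0.8]})
        r, _, tau, _ = ld_measure_correlation(rec)
        assert r == pytest.approx(1.0)
        assert tau == pytest.approx(1.0)

    def test_anti_monotone(self):
        rec = pd.DataFrame({"dprime": [0.1, 0.4, 0.8], "r2": [0.9, 0.5, 0.2]})
        _, _, tau, _ = ld_measure_correlation(rec)
        assert tau == pytest.approx(-1.0)

    def test_tau_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.random(20)
        y = rng.random(20)
        rec = pd.DataFrame({"dprime": x, "r2": y})
        _, _, tau, _ = ld_measure_correlation(rec)
        conc = disc = 0
        for i, j in itertools.combinations(range(20), 2):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            conc += s > 0
            disc += s < 0
        assert tau == pytest.approx((conc - disc) / (20 * 19 / 2), abs=1e-12)

    def test_zero_variance_flagged(self):
        rec = pd.DataFrame({"dprime": [0.5] * 5, "r2": [0.1, 0.2, 0.3, 0.4, 0.5]})
        with pytest.raises(ValueError):
            ld_measure_correlation(rec)
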