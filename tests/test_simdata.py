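import filecmp

import numpy as np
import pytest

from msatld.bottleneck import TPMParams
from msatld.diversity import expected_heterozygosity
from msatld.genodata import ValidationError, read_genepop, read_marker_map
from msatld.ld import em_haplotype_frequencies, syntenic_ld_scan
from msatld.popstruct import pairwise_fst
from msatld.simdata import (
    DemographicScenario,
    PopulationSpec,
    default_marker_map,
    export_dataset,
    habitat_survey_scenario,
    habitat_units,
    preset_scenarios,
    simulate_metapopulation,
)


def small_scenario(mu=1e-3, n_loci_map=None, **pop_kwargs):
    mm = n_loci_map or default_marker_map()
    defaults = dict(name="d1", habitat="pond", coastal=False, ne=30,
                    founder_count=10, founding_time=20, migration_rate=0.0)
    defaults.update(pop_kwargs)
    return DemographicScenario(
        ancestral_ne=50,
        populations=[PopulationSpec(**defaults)],
        marker_map=mm,
        tpm=TPMParams(p_single=0.9, mean_multistep=3.5, mu=mu),
        burn_in=10,
    )


class TestMarkerLayout:
    def test_default_map_shape(self):
        mm = default_marker_map()
        assert len(mm.markers) == 109
        sizes = mm.table.groupby("lg").size()
        assert len(sizes) == 20
        assert sizes.min() >= 2 and sizes.max() <= 13
        gaps = mm.adjacent_interval_summary()
        assert 1.5 < gaps["mean_mb"] < 4.0

    def test_map_deterministic(self):
        a = default_marker_map().table
        b = default_marker_map().table
        assert a.equals(b)


class TestEngineInvariants:
    def test_zero_mutation_monomorphic_founders(self):
        scn = small_scenario(mu=0.0)
        ds, _, _ = simulate_metapopulation(scn, seed=0)
        _, he = expected_heterozygosity(ds, "d1")
        assert he == 0.0

    def test_drift_never_creates_alleles(self):
        scn = small_scenario(mu=0.0)
        # seed ancestral variation by hand: mutation off afterwards
        ds, _, truth = simulate_metapopulation(scn, seed=1)
        # with mu=0 ancestral pool is monomorphic at the baseline state
        for pop in ds.populations:
            assert np.unique(pop.genotypes).size == len(np.unique(ds.motif_bp)) or \
                np.unique(pop.genotypes).size <= ds.n_loci  # one allele per locus
        alleles = {
            int(a) for pop in ds.populations for a in np.unique(pop.genotypes)
        }
        expected = {30 * int(m) + 100 for m in np.unique(ds.motif_bp)}
        assert alleles <= expected

    def test_equilibrium_heterozygosity_matches_smm_theory(self):
        # theta = 4 * 30 * 0.005 = 0.6 -> E[H] = 1 - 1/sqrt(2.2) ~ 0.326
        scn = DemographicScenario(
            ancestral_ne=30,
            populations=[PopulationSpec("e1", "marine", False, 30, 30, 0, 0.0)],
            marker_map=default_marker_map(),
            tpm=TPMParams(p_single=1.0, mean_multistep=3.5, mu=0.005),
            burn_in=60,
        )
        hs = []
        for seed in range(4):
            ds, _, _ = simulate_metapopulation(scn, seed=seed)
            _, he = expected_heterozygosity(ds, "e1")
            hs.append(he)
        expected = 1 - 1 / np.sqrt(1 + 8 * 30 * 0.005)
        assert abs(np.mean(hs) - expected) < 0.05

    def test_founder_count_cannot_exceed_ancestral(self):
        scn = small_scenario(founder_count=200)
        with pytest.raises(ValidationError):
            simulate_metapopulation(scn, seed=0)

    def test_isolation_time_increases_differentiation(self):
        # two isolated daughters founded longer ago drift further apart
        def fst_at(t, seed):
            mm = default_marker_map()
            scn = DemographicScenario(
                ancestral_ne=60,
                populations=[
                    PopulationSpec("a", "lake", False, 30, 30, t, 0.0),
                    PopulationSpec("b", "lake", False, 30, 30, t, 0.0),
                ],
                marker_map=mm,
                tpm=TPMParams(mu=1e-3),
                burn_in=10,
            )
            ds, _, _ = simulate_metapopulation(scn, seed=seed)
            return pairwise_fst(ds, "a", "b")

        short = np.mean([fst_at(5, s) for s in range(6)])
        long = np.mean([fst_at(60, 100 + s) for s in range(6)])
        assert long > short


class TestTruth:
    def test_truth_allele_freqs_match_dataset_tallies(self):
        scn = small_scenario(mu=2e-3)
        ds, mm, truth = simulate_metapopulation(scn, seed=3)
        pop = ds.populations[0]
        for l, locus in enumerate(ds.loci):
            tallied = {}
            for ind in range(pop.n_individuals):
                for a in pop.genotypes[ind, l]:
                    tallied[int(a)] = tallied.get(int(a), 0) + 1
            total = sum(tallied.values())
            rec = truth.allele_freqs[(pop.name, locus)]
            assert set(rec) == set(tallied)
            for a, f in rec.items():
                assert f == pytest.approx(tallied[a] / total)

    def test_truth_haplotype_margins_match_em_margins(self):
        scn = small_scenario(mu=2e-3)
        ds, mm, truth = simulate_metapopulation(scn, seed=4)
        pairs = [k for k in truth.haplotype_freqs if k[0] == "d1"]
        checked = 0
        for _, la, lb in pairs:
            ua, ub, joint = truth.haplotype_freqs[("d1", la, lb)]
            if len(ua) < 2 or len(ub) < 2:
                continue
            h = em_haplotype_frequencies(ds, "d1", la, lb)
            assert np.allclose(h.margin_a, joint.sum(axis=1), atol=1e-8)
            assert np.allclose(h.margin_b, joint.sum(axis=0), atol=1e-8)
            checked += 1
            if checked > 5:
                break
        assert checked > 0


class TestPresets:
    def test_preset_keys_and_rescale(self):
        presets = preset_scenarios(rescale=10)
        assert set(presets) == {
            "marine", "coastal", "inland_lake", "inland_pond", "inland_pond_recent"
        }
        pond = presets["inland_pond"].populations[0]
        assert pond.ne >= pond.n_sample
        marine = presets["marine"].populations[0]
        assert marine.founding_time == 0

    def test_pond_lower_diversity_higher_ld_than_marine(self):
        presets = preset_scenarios(rescale=20)
        he = {}
        dp = {}
        for key, name in [("marine", "marine1"), ("inland_pond", "pond1")]:
            ds, mm, _ = simulate_metapopulation(presets[key], seed=5)
            _, he[key] = expected_heterozygosity(ds, name)
            rec = syntenic_ld_scan(ds, mm, name)
            dp[key] = rec.dprime.mean()
        assert he["inland_pond"] < he["marine"]
        assert dp["inland_pond"] > dp["marine"]

    def test_pooled_marine_dprime_below_per_population_average(self):
        # pooling undifferentiated populations doubles the sample size,
        # shrinking the finite-sample upward bias of multiallelic D'
        scn = habitat_survey_scenario(n_per_habitat=2, rescale=20)
        ds, mm, _ = simulate_metapopulation(scn, seed=13)
        pooled = syntenic_ld_scan(
            ds, mm, "marine", members=["marine1", "marine2"]
        )["dprime"].mean()
        per_pop = np.mean(
            [
                syntenic_ld_scan(ds, mm, name)["dprime"].mean()
                for name in ("marine1", "marine2")
            ]
        )
        assert pooled < per_pop

    def test_habitat_units_classification(self):
        scn = habitat_survey_scenario(n_per_habitat=1, rescale=50)
        ds, _, _ = simulate_metapopulation(scn, seed=6)
        units = habitat_units(ds)
        assert units["marine"] == ["marine1"]
        assert units["coastal"] == ["coastal1"]
        assert units["lake"] == ["lake1"]
        assert units["pond"] == ["pond1"]


class TestExport:
    def test_roundtrip_and_seed_determinism(self, tmp_path):
        scn = small_scenario(mu=2e-3)
        ds, mm, truth = simulate_metapopulation(scn, seed=9)
        out1 = tmp_path / "run1"
        out2 = tmp_path / "run2"
        export_dataset(ds, mm, out1, truth)
        back = read_genepop(out1 / "genotypes.gen", out1 / "habitats.tsv")
        assert back.loci == ds.loci
        assert np.array_equal(
            np.sort(back.populations[0].genotypes, axis=2),
            np.sort(ds.populations[0].genotypes, axis=2),
        )
        mm_back = read_marker_map(out1 / "marker_map.tsv")
        assert mm_back.markers == mm.markers
        ds2, mm2, truth2 = simulate_metapopulation(small_scenario(mu=2e-3), seed=9)
        export_dataset(ds2, mm2, out2, truth2)
        for fname in ("genotypes.gen", "marker_map.tsv", "habitats.tsv", "truth.json"):
            assert filecmp.cmp(out1 / fname, out2 / fname, shallow=False), fname
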