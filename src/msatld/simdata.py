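"""Forward-time simulator of habitat-structured microsatellite metapopulations.

The generator emulates the survey design the analysis modules expect: ~109
microsatellites spread over 20 linkage groups, diploid samples of 24
individuals per population, and a demographic contrast between a large
connected marine pool, recently founded coastal freshwater populations that
keep exchanging migrants with it, and small inland freshwater isolates
founded by few colonists long ago.

Engine: diploid Wright-Fisher with multi-locus recombination and two-phase
(TPM) microsatellite mutation.  The ancestral pool is initialized at
mutation-drift equilibrium from an exact coalescent sample (independent loci)
and run forward for a short burn-in so that within-linkage-group LD reaches
its drift-recombination quasi-equilibrium; daughter populations are founded
from it at stated times with stated founder counts, optionally receiving
migrants every generation.  Recombination between adjacent syntenic markers
occurs with probability min(0.5, rate_per_mb * distance); repeat counts are
bounded with reflecting boundaries, as is standard in microsatellite
simulators.

An Ne-rescaling knob (divide Ne, founder counts and times by c; multiply the
mutation, migration and recombination rates by c) preserves the scaled
parameters theta = 4*Ne*mu, 4*Ne*m and 4*Ne*r so the test suite runs in
minutes.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bottleneck import TPMParams, sample_coalescent_tpm, tpm_steps
from .genodata import (
    GenotypeDataset,
    MarkerMap,
    Population,
    ValidationError,
    write_genepop,
    write_habitat_table,
    write_marker_map,
)


@dataclass
class PopulationSpec:
    """One sampled population of the scenario.

    ``founding_time`` is in generations before sampling; 0 means the
    population is the ancestral pool itself (a direct sample of it).
    ``migration_rate`` is the per-generation probability that an individual
    is replaced by a migrant from the ancestral pool.
    """

    name: str
    habitat: str
    coastal: bool
    ne: int
    founder_count: int
    founding_time: int
    migration_rate: float = 0.0
    n_sample: int = 24


@dataclass
class DemographicScenario:
    ancestral_ne: int
    populations: list[PopulationSpec]
    marker_map: MarkerMap
    tpm: TPMParams = field(default_factory=TPMParams)
    recomb_rate_per_mb: float = 0.01  # 1 cM/Mb
    repeat_bounds: tuple[int, int] = (5, 60)
    burn_in: int = 200
    allele_offset_bp: int = 100

    def validate(self) -> None:
        for spec in self.populations:
            if spec.founder_count > self.ancestral_ne:
                raise ValidationError(
                    f"{spec.name}: founder count {spec.founder_count} exceeds "
                    f"ancestral Ne {self.ancestral_ne}"
                )
            if not 0.0 <= spec.migration_rate < 1.0:
                raise ValidationError(f"{spec.name}: migration rate out of [0, 1)")
            if spec.founding_time < 0:
                raise ValidationError(f"{spec.name}: negative founding time")
        if (self.marker_map.table["position_mb"] < 0).any():
            raise ValidationError("negative marker positions")

    def rescaled(self, c: float) -> "DemographicScenario":
        """Divide population sizes and times by c; multiply mutation,
        migration and recombination rates by c (theta-preserving)."""
        if c <= 0:
            raise ValueError("rescale factor must be positive")
        pops = [
            replace(
                spec,
                ne=max(spec.n_sample, round(spec.ne / c)),
                founder_count=max(2, round(spec.founder_count / c)),
                founding_time=(
                    0 if spec.founding_time == 0 else max(1, round(spec.founding_time / c))
                ),
                migration_rate=min(0.5, spec.migration_rate * c),
            )
            for spec in self.populations
        ]
        tpm = TPMParams(
            p_single=self.tpm.p_single,
            mean_multistep=self.tpm.mean_multistep,
            mu=min(0.05, self.tpm.mu * c),
        )
        n_sample_max = max((s.n_sample for s in self.populations), default=24)
        return replace(
            self,
            ancestral_ne=max(n_sample_max, round(self.ancestral_ne / c)),
            populations=pops,
            tpm=tpm,
            recomb_rate_per_mb=self.recomb_rate_per_mb * c,
            burn_in=max(10, round(self.burn_in / c)),
        )


@dataclass
class SimTruth:
    """Realized (sampled-chromosome) frequencies for oracle checks."""

    scenario: DemographicScenario
    allele_freqs: dict  # (pop, locus) -> {allele_code: frequency}
    haplotype_freqs: dict  # (pop, locusA, locusB) -> (alleles_a, alleles_b, freq)


# ---------------------------------------------------------------------------
# Marker layout
# ---------------------------------------------------------------------------

_LG_SIZES = (13, 12, 10, 9, 8, 7, 6, 6, 5, 5, 4, 4, 3, 3, 3, 3, 2, 2, 2, 2)


def default_marker_map(motif_bp: int = 4) -> MarkerMap:
    """109 markers on 20 linkage groups with spacings of 0.001-11.5 Mb
    (mean ~2.7 Mb), mirroring a sparse microsatellite linkage map.  The
    layout is deterministic (internally seeded)."""
    rng = np.random.default_rng(20140812)
    rows = []
    idx = 1
    for lg, size in enumerate(_LG_SIZES, start=1):
        gaps = np.clip(rng.exponential(2.7, size=size - 1), 0.001, 11.5)
        pos = np.concatenate([[0.0], np.cumsum(gaps)])
        for p in pos:
            rows.append(
                {
                    "marker": f"M{idx:03d}",
                    "lg": f"LG{lg}",
                    "position_mb": round(float(p), 3),
                    "motif_bp": motif_bp,
                }
            )
            idx += 1
    return MarkerMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Wright-Fisher engine
# ---------------------------------------------------------------------------

class _Engine:
    def __init__(self, scenario: DemographicScenario, rng: np.random.Generator):
        self.scn = scenario
        self.rng = rng
        tab = scenario.marker_map.table
        order = tab.sort_values(["lg", "position_mb"], kind="stable")
        self.loci = order["marker"].tolist()
        self.motifs = (
            order["motif_bp"].to_numpy(dtype=int)
            if "motif_bp" in order.columns
            else np.full(len(self.loci), 4)
        )
        pos = order["position_mb"].to_numpy(dtype=float)
        lg = order["lg"].to_numpy()
        L = len(self.loci)
        # switch probability entering locus l; 0.5 at LG starts gives each LG
        # an independent random starting phase
        prob = np.full(L, 0.5)
        for l in range(1, L):
            if lg[l] == lg[l - 1]:
                prob[l] = min(0.5, scenario.recomb_rate_per_mb * (pos[l] - pos[l - 1]))
        self.switch_prob = prob
        self.L = L
        self.n_reflect = 0

    # Coalescent init sample size cap: for very large pools an equilibrium
    # sample of this many copies is drawn and resampled up to 2N (one extra
    # round of multinomial noise, smoothed out by the forward burn-in).
    INIT_CAP = 600

    def equilibrium_init(self, n_diploid: int) -> np.ndarray:
        """Coalescent-equilibrium haplotypes (2N, L), loci independent."""
        theta = 4.0 * n_diploid * self.scn.tpm.mu
        n_copies = 2 * n_diploid
        if theta == 0:  # no mutation: monomorphic pool at the baseline state
            return np.full((n_copies, self.L), 30, dtype=np.int64)
        n_init = min(n_copies, self.INIT_CAP)
        sample = sample_coalescent_tpm(
            n_init, theta, self.scn.tpm, self.L, self.rng
        )  # (L, n_init)
        h = sample.T
        if n_init < n_copies:
            pick = self.rng.integers(0, n_init, size=n_copies)
            h = h[pick]
        return self._reflect(h.copy())

    def _reflect(self, h: np.ndarray) -> np.ndarray:
        lo, hi = self.scn.repeat_bounds
        for _ in range(8):
            below = h < lo
            above = h > hi
            if not (below.any() or above.any()):
                break
            self.n_reflect += int(below.sum() + above.sum())
            h[below] = 2 * lo - h[below]
            h[above] = 2 * hi - h[above]
        np.clip(h, lo, hi, out=h)
        return h

    def _gametes(self, h: np.ndarray, parents: np.ndarray) -> np.ndarray:
        switches = self.rng.random((parents.size, self.L)) < self.switch_prob
        phase = np.cumsum(switches, axis=1) & 1
        return h[2 * parents[:, None] + phase, np.arange(self.L)[None, :]]

    def next_generation(self, h: np.ndarray, n_offspring: int) -> np.ndarray:
        n_parents = h.shape[0] // 2
        mothers = self.rng.integers(0, n_parents, n_offspring)
        fathers = self.rng.integers(0, n_parents, n_offspring)
        new = np.empty((2 * n_offspring, self.L), dtype=h.dtype)
        new[0::2] = self._gametes(h, mothers)
        new[1::2] = self._gametes(h, fathers)
        mask = self.rng.random(new.shape) < self.scn.tpm.mu
        n_mut = int(mask.sum())
        if n_mut:
            new[mask] += tpm_steps(n_mut, self.scn.tpm, self.rng)
            new = self._reflect(new)
        return new

    def migrate(self, h: np.ndarray, anc: np.ndarray, rate: float) -> np.ndarray:
        if rate <= 0:
            return h
        n = h.shape[0] // 2
        mig = np.where(self.rng.random(n) < rate)[0]
        if mig.size:
            src = self.rng.integers(0, anc.shape[0] // 2, mig.size)
            h[2 * mig] = anc[2 * src]
            h[2 * mig + 1] = anc[2 * src + 1]
        return h


def simulate_metapopulation(
    scenario: DemographicScenario, seed: int | None = None
) -> tuple[GenotypeDataset, MarkerMap, SimTruth]:
    """Run the scenario and sample a :class:`GenotypeDataset`.

    Returns the dataset (allele codes in bp: repeat count * motif + offset),
    the marker map (locus order matches the dataset) and a :class:`SimTruth`
    with the sampled chromosomes' realized allele and two-locus haplotype
    frequencies for every syntenic pair.
    """
    scenario.validate()
    rng = np.random.default_rng(seed)
    eng = _Engine(scenario, rng)

    anc = eng.equilibrium_init(scenario.ancestral_ne)
    for _ in range(scenario.burn_in):
        anc = eng.next_generation(anc, scenario.ancestral_ne)

    timeline = max((s.founding_time for s in scenario.populations), default=0)
    states: dict[str, np.ndarray] = {}

    def _anc_needed(now: int) -> bool:
        for s in scenario.populations:
            if s.founding_time == 0 or s.founding_time <= now:
                return True  # founding still pending, or final direct sample
            if s.name in states and s.migration_rate > 0:
                return True
        return False

    for t in range(timeline, 0, -1):
        if _anc_needed(t):
            anc = eng.next_generation(anc, scenario.ancestral_ne)
        for spec in scenario.populations:
            if spec.founding_time == t and spec.name not in states:
                founders = rng.choice(
                    scenario.ancestral_ne, size=spec.founder_count, replace=False
                )
                rows = np.stack([2 * founders, 2 * founders + 1], axis=1).ravel()
                states[spec.name] = anc[rows].copy()
            elif spec.name in states:
                h = eng.next_generation(states[spec.name], spec.ne)
                states[spec.name] = eng.migrate(h, anc, spec.migration_rate)

    populations = []
    sampled_haplos: dict[str, np.ndarray] = {}
    for spec in scenario.populations:
        h = states.get(spec.name, anc)  # founding_time == 0: the pool itself
        n_avail = h.shape[0] // 2
        if spec.n_sample > n_avail:
            raise ValidationError(
                f"{spec.name}: cannot sample {spec.n_sample} from {n_avail}"
            )
        pick = rng.choice(n_avail, size=spec.n_sample, replace=False)
        rows = np.stack([2 * pick, 2 * pick + 1], axis=1).ravel()
        haplo = h[rows]
        sampled_haplos[spec.name] = haplo
        codes = haplo * eng.motifs[None, :] + scenario.allele_offset_bp
        geno = np.empty((spec.n_sample, eng.L, 2), dtype=np.int32)
        geno[:, :, 0] = codes[0::2]
        geno[:, :, 1] = codes[1::2]
        populations.append(
            Population(
                spec.name,
                spec.habitat,
                spec.coastal,
                geno,
                [f"{spec.name}_{i}" for i in range(spec.n_sample)],
            )
        )

    dataset = GenotypeDataset(
        loci=list(eng.loci), populations=populations, motif_bp=eng.motifs.copy()
    )
    dataset.validate()
    marker_map = MarkerMap(
        scenario.marker_map.table.set_index("marker").loc[eng.loci].reset_index()
    )
    truth = _build_truth(scenario, dataset, marker_map, sampled_haplos, eng)
    return dataset, marker_map, truth


def _build_truth(scenario, dataset, marker_map, sampled_haplos, eng) -> SimTruth:
    allele_freqs = {}
    hap_freqs = {}
    pairs = marker_map.syntenic_pairs(dataset.loci)
    locus_idx = {name: i for i, name in enumerate(dataset.loci)}
    for spec in scenario.populations:
        haplo = sampled_haplos[spec.name]
        codes = haplo * eng.motifs[None, :] + scenario.allele_offset_bp
        for l, locus in enumerate(dataset.loci):
            alleles, counts = np.unique(codes[:, l], return_counts=True)
            allele_freqs[(spec.name, locus)] = {
                int(a): float(c) / codes.shape[0] for a, c in zip(alleles, counts)
            }
        for row in pairs.itertuples(index=False):
            ia, ib = locus_idx[row.locusA], locus_idx[row.locusB]
            a = codes[:, ia]
            b = codes[:, ib]
            ua, a_i = np.unique(a, return_inverse=True)
            ub, b_i = np.unique(b, return_inverse=True)
            joint = np.zeros((len(ua), len(ub)))
            np.add.at(joint, (a_i, b_i), 1.0)
            hap_freqs[(spec.name, row.locusA, row.locusB)] = (
                ua,
                ub,
                joint / a.size,
            )
    return SimTruth(copy.deepcopy(scenario), allele_freqs, hap_freqs)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_scenarios(rescale: float = 1.0) -> dict[str, DemographicScenario]:
    """Single-population scenario templates for the four habitat conditions.

    * marine   -- the large connected pool itself (Ne 5000);
    * coastal  -- freshwater but recently founded (500 generations ago, 200
      founders, Ne 1000) with continuing migration m = 0.01 from the pool;
    * inland_lake -- founded 2000 generations ago by 50 colonists, Ne 500,
      isolated since;
    * inland_pond -- founded 2000 generations ago by 20 colonists, Ne 100,
      isolated since (mutation-drift equilibrium at its own small theta);
    * inland_pond_recent -- the same founder event sampled 50 generations
      after founding, i.e. in the bottleneck phase where the transient
      signatures (heterozygosity excess, depressed M-ratio) are present.

    Expected diversity ordering is marine ~ coastal > lake > pond and LD
    ordering pond > lake > marine.  ``rescale`` applies Ne rescaling for fast
    runs (see :meth:`DemographicScenario.rescaled`).
    """
    mm = default_marker_map()
    specs = {
        "marine": PopulationSpec("marine1", "marine", False, 5000, 5000, 0, 0.0),
        "coastal": PopulationSpec("coastal1", "lake", True, 1000, 200, 500, 0.01),
        "inland_lake": PopulationSpec("lake1", "lake", False, 500, 50, 2000, 0.0),
        "inland_pond": PopulationSpec("pond1", "pond", False, 100, 20, 2000, 0.0),
        "inland_pond_recent": PopulationSpec("pond1", "pond", False, 100, 20, 50, 0.0),
    }
    out = {}
    for key, spec in specs.items():
        scn = DemographicScenario(
            ancestral_ne=5000, populations=[spec], marker_map=mm
        )
        out[key] = scn.rescaled(rescale) if rescale != 1.0 else scn
    return out


def habitat_survey_scenario(
    n_per_habitat: int = 2, rescale: float = 1.0
) -> DemographicScenario:
    """A joint scenario with ``n_per_habitat`` populations of each preset,
    founded independently from one shared ancestral pool."""
    mm = default_marker_map()
    pops = []
    for i in range(1, n_per_habitat + 1):
        pops.append(PopulationSpec(f"marine{i}", "marine", False, 5000, 5000, 0, 0.0))
        pops.append(PopulationSpec(f"coastal{i}", "lake", True, 1000, 200, 500, 0.01))
        pops.append(PopulationSpec(f"lake{i}", "lake", False, 500, 50, 2000, 0.0))
        pops.append(PopulationSpec(f"pond{i}", "pond", False, 100, 20, 2000, 0.0))
    scn = DemographicScenario(ancestral_ne=5000, populations=pops, marker_map=mm)
    return scn.rescaled(rescale) if rescale != 1.0 else scn


def habitat_units(dataset: GenotypeDataset) -> dict[str, list[str]]:
    """Analysis units for habitat comparisons: marine, inland lake, inland
    pond, and coastal freshwater (all coastal-flagged populations)."""
    units: dict[str, list[str]] = {"marine": [], "lake": [], "pond": [], "coastal": []}
    for p in dataset.populations:
        if p.habitat == "marine":
            units["marine"].append(p.name)
        elif p.coastal:
            units["coastal"].append(p.name)
        elif p.habitat in ("lake", "river"):
            units["lake"].append(p.name)
        elif p.habitat == "pond":
            units["pond"].append(p.name)
    return {k: v for k, v in units.items() if v}


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_dataset(dataset: GenotypeDataset, marker_map: MarkerMap, out_dir,
                   truth: SimTruth | None = None) -> dict[str, str]:
    """Write GenePop genotypes, marker map, habitat table (and, if given, the
    truth record as JSON) into ``out_dir``; returns the file paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genepop": str(out / "genotypes.gen"),
        "marker_map": str(out / "marker_map.tsv"),
        "habitats": str(out / "habitats.tsv"),
    }
    write_genepop(dataset, paths["genepop"])
    write_marker_map(marker_map, paths["marker_map"])
    write_habitat_table(dataset, paths["habitats"])
    if truth is not None:
        paths["truth"] = str(out / "truth.json")
        payload = {
            "scenario": {
                "ancestral_ne": truth.scenario.ancestral_ne,
                "recomb_rate_per_mb": truth.scenario.recomb_rate_per_mb,
                "mu": truth.scenario.tpm.mu,
                "p_single": truth.scenario.tpm.p_single,
                "mean_multistep": truth.scenario.tpm.mean_multistep,
                "populations": [
                    {
                        "name": s.name,
                        "habitat": s.habitat,
                        "coastal": s.coastal,
                        "ne": s.ne,
                        "founder_count": s.founder_count,
                        "founding_time": s.founding_time,
                        "migration_rate": s.migration_rate,
                        "n_sample": s.n_sample,
                    }
                    for s in truth.scenario.populations
                ],
            },
            "allele_freqs": {
                f"{pop}|{locus}": freqs
                for (pop, locus), freqs in truth.allele_freqs.items()
            },
        }
        with open(paths["truth"], "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    return paths
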