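"""End-to-end orchestration: configuration, stage sequencing, TSV reports.

Stages run in dependency order (data loading/simulation, then diversity, LD,
structure and bottleneck independently, then comparisons, which need the LD
records).  Every report carries the tool version, the run seed and a config
echo in comment headers; a JSON manifest lists outputs with checksums.  All
randomness flows from the single config seed through named substreams, so a
rerun with the same config is byte-identical and disabling one stage never
changes another stage's numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bottleneck, compare, diversity, ld, popstruct, simdata
from .genodata import GenotypeDataset, MarkerMap, read_genepop, read_marker_map

log = logging.getLogger("msatld")


@dataclass
class RunConfig:
    # inputs: either file paths ...
    genepop: str | None = None
    marker_map: str | None = None
    habitat_table: str | None = None
    # ... or a simulation preset
    simulate_preset: str | None = None  # marine|coastal|inland_lake|inland_pond|survey
    rescale: float = 50.0
    n_per_habitat: int = 2
    # stage toggles
    run_diversity: bool = True
    run_ld: bool = True
    run_structure: bool = True
    run_bottleneck: bool = True
    run_compare: bool = True
    # LD options
    measure_source: str = "EM"  # EM | composite
    exclude_rare: bool = False
    # sampling effort
    n_perm: int = 1000
    n_boot: int = 1000
    n_iter_het: int = 200
    n_iter_m: int = 2000
    seed: int = 0
    out_dir: str = "msatld_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_report(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    # echo only fields that influence the numbers: stage toggles and the
    # output directory are excluded so identical analyses are byte-identical
    echo = {
        k: v
        for k, v in asdict(config).items()
        if k != "out_dir" and not k.startswith("run_")
    }
    with open(path, "w") as fh:
        fh.write(f"# msatld {__version__}\n")
        fh.write(f"# seed: {config.seed}\n")
        fh.write(f"# config: {json.dumps(echo, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_inputs(config: RunConfig, rng: np.random.Generator):
    if config.simulate_preset:
        seed = int(rng.integers(2**31 - 1))
        if config.simulate_preset == "survey":
            scn = simdata.habitat_survey_scenario(
                n_per_habitat=config.n_per_habitat, rescale=config.rescale
            )
        else:
            presets = simdata.preset_scenarios(rescale=config.rescale)
            if config.simulate_preset not in presets:
                raise ValueError(
                    f"unknown preset {config.simulate_preset!r}; "
                    f"choose from {sorted(presets)} or 'survey'"
                )
            scn = presets[config.simulate_preset]
        dataset, marker_map, truth = simdata.simulate_metapopulation(scn, seed=seed)
        return dataset, marker_map, truth
    if not (config.genepop and config.marker_map and config.habitat_table):
        raise ValueError(
            "either simulate_preset or all of genepop/marker_map/habitat_table "
            "must be set"
        )
    dataset = read_genepop(config.genepop, config.habitat_table)
    marker_map = read_marker_map(config.marker_map)
    dataset.set_motifs_from_map(marker_map)
    return dataset, marker_map, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: list[Path] = []
    # independent named substreams so stage toggles cannot interact
    root = np.random.SeedSequence(config.seed)
    named = root.spawn(6)
    rng_data, rng_div, rng_ld, rng_struct, rng_bot, rng_cmp = (
        np.random.default_rng(s) for s in named
    )

    try:
        stage = "genodata"
        dataset, marker_map, truth = _load_inputs(config, rng_data)
        if config.simulate_preset:
            simdata.export_dataset(dataset, marker_map, out / "inputs", truth)
            outputs += sorted((out / "inputs").glob("*"))

        ld_records = None
        if config.run_diversity:
            stage = "diversity"
            log.info("diversity stage")
            table = diversity.diversity_table(
                dataset, n_boot=config.n_boot, seed=int(rng_div.integers(2**31 - 1))
            )
            _write_report(table, out / "diversity.tsv", config)
            outputs.append(out / "diversity.tsv")

        if config.run_ld or config.run_compare:
            stage = "ld"
            log.info("ld stage")
            frames = []
            units = {p.name: None for p in dataset.populations}
            units.update(simdata.habitat_units(dataset))
            for unit, members in units.items():
                rec = ld.syntenic_ld_scan(
                    dataset, marker_map, unit,
                    exclude_rare=config.exclude_rare,
                    measure_source=config.measure_source,
                    members=members,
                )
                if not rec.empty:
                    frames.append(rec)
            ld_records = pd.concat(frames, ignore_index=True)
        if config.run_ld:
            _write_report(ld_records, out / "ld_pairs.tsv", config)
            outputs.append(out / "ld_pairs.tsv")
            bins = []
            decays = []
            for unit, rec in ld_records.groupby("unit", sort=False):
                b = ld.bin_ld_by_distance(rec)
                b.insert(0, "unit", unit)
                bins.append(b)
                try:
                    fit = ld.fit_ld_decay(rec)
                    decays.append(
                        {
                            "unit": unit,
                            "intercept": fit.intercept,
                            "slope": fit.slope,
                            "r_squared": fit.r_squared,
                            "p": fit.p_value,
                            "half_length_mb": fit.half_length_mb,
                            "n_pairs": fit.n_pairs,
                        }
                    )
                except ValueError:
                    pass
            _write_report(pd.concat(bins, ignore_index=True), out / "ld_bins.tsv", config)
            outputs.append(out / "ld_bins.tsv")
            _write_report(pd.DataFrame(decays), out / "ld_decay.tsv", config)
            outputs.append(out / "ld_decay.tsv")

        if config.run_structure:
            stage = "structure"
            log.info("structure stage")
            fst = popstruct.fst_matrix(
                dataset,
                n_perm=config.n_perm if len(dataset.populations) > 1 else 0,
                seed=int(rng_struct.integers(2**31 - 1)),
            )
            _write_report(fst, out / "fst.tsv", config)
            outputs.append(out / "fst.tsv")
            habitats = {p.name: p.habitat for p in dataset.populations}
            if len(set(habitats.values())) > 1:
                res = popstruct.amova(
                    dataset, habitats, n_perm=min(config.n_perm, 200),
                    seed=int(rng_struct.integers(2**31 - 1)), name="habitat",
                )
                _write_report(res.as_frame(), out / "amova.tsv", config)
                outputs.append(out / "amova.tsv")

        if config.run_bottleneck:
            stage = "bottleneck"
            log.info("bottleneck stage")
            rep = bottleneck.bottleneck_report(
                dataset,
                n_iter_het=config.n_iter_het,
                n_iter_m=config.n_iter_m,
                seed=int(rng_bot.integers(2**31 - 1)),
            )
            _write_report(rep, out / "bottleneck.tsv", config)
            outputs.append(out / "bottleneck.tsv")

        if config.run_compare:
            stage = "compare"
            log.info("compare stage")
            unit_names = set(simdata.habitat_units(dataset))
            hab_rec = ld_records[ld_records["unit"].isin(unit_names)]
            pop_rec = ld_records[~ld_records["unit"].isin(unit_names)]
            tests = []
            hab_groups = {
                u: g["dprime"].to_numpy() for u, g in hab_rec.groupby("unit")
            }
            keys = sorted(hab_groups)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    u, z, p = compare.mann_whitney(hab_groups[keys[i]], hab_groups[keys[j]])
                    tests.append(
                        {
                            "test": "mann_whitney",
                            "grouping": f"{keys[i]} vs {keys[j]}",
                            "statistic": z,
                            "df": np.nan,
                            "p": p,
                        }
                    )
            pop_groups = [g["dprime"].to_numpy() for _, g in pop_rec.groupby("unit")]
            if len(pop_groups) >= 2:
                h, dfree, p = compare.kruskal_wallis(pop_groups)
                tests.append(
                    {
                        "test": "kruskal_wallis",
                        "grouping": "all populations",
                        "statistic": h,
                        "df": dfree,
                        "p": p,
                    }
                )
            if tests:
                _write_report(
                    compare.comparison_report(tests), out / "compare.tsv", config
                )
                outputs.append(out / "compare.tsv")

    except Exception as exc:  # annotate failures with the stage name
        log.removeHandler(handler)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    finally:
        if handler in log.handlers:
            log.removeHandler(handler)
        handler.close()

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "outputs": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in outputs
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
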