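"""Compare genome-wide LD between habitat types.

Simulates two populations per habitat condition, pools genotypes within each
habitat unit, and compares pooled syntenic D' between habitats with
Mann-Whitney tests (Bonferroni-adjusted) and a nested ANCOVA controlling for
marker distance.  The expected ordering is pond > lake > marine with the
coastal freshwater unit close to marine.
"""

import pandas as pd

from msatld import (
    ancova_ld,
    habitat_survey_scenario,
    habitat_units,
    mann_whitney,
    simulate_metapopulation,
    syntenic_ld_scan,
)
from msatld.compare import comparison_report

scenario = habitat_survey_scenario(n_per_habitat=2, rescale=10)
dataset, marker_map, _ = simulate_metapopulation(scenario, seed=51)
units = habitat_units(dataset)

pooled = {}
for unit, members in units.items():
    rec = syntenic_ld_scan(dataset, marker_map, unit, members=members)
    pooled[unit] = rec
    print(f"{unit:>8}: mean pooled syntenic D' = {rec.dprime.mean():.3f} "
          f"({len(rec)} pairs)")

tests = []
for other in ("lake", "pond", "coastal"):
    u, z, p = mann_whitney(pooled[other]["dprime"], pooled["marine"]["dprime"])
    tests.append({"test": "mann_whitney", "grouping": f"{other} vs marine",
                  "statistic": z, "df": None, "p": p})
print("\n" + comparison_report(tests).round(4).to_string(index=False))

# per-population records for the nested ANCOVA
frames = []
for pop in dataset.populations:
    rec = syntenic_ld_scan(dataset, marker_map, pop.name)
    rec["population"] = pop.name
    rec["habitat"] = (
        "coastal" if pop.coastal else pop.habitat
    )
    frames.append(rec)
records = pd.concat(frames, ignore_index=True)
print("\nANCOVA of D' on habitat + population(habitat) + distance:")
print(ancova_ld(records).round(4).to_string(index=False))
print(
    "\nPositive Z against marine for the inland units with adjusted p below"
    "\n0.05 reproduces the habitat contrast; the distance covariate explains"
    "\nalmost none of the variance on a sparse map."
)
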