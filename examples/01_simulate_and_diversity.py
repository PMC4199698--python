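"""Simulate the four habitat presets and tabulate genetic diversity.

Builds one population per habitat condition (marine, coastal freshwater,
inland lake, inland pond) from a shared ancestral pool, then prints the
standard variability table: polymorphic loci (npl), allele counts (A),
rarefied allelic richness (Ar), observed/expected heterozygosity and F_IS.
Expect marine ~ coastal > lake > pond in H_E and Ar: the inland isolates
have lost diversity to founder events and small-Ne drift.
"""

from msatld import diversity_table, habitat_survey_scenario, simulate_metapopulation

scenario = habitat_survey_scenario(n_per_habitat=1, rescale=25)
dataset, marker_map, truth = simulate_metapopulation(scenario, seed=11)

table = diversity_table(dataset, n_boot=200, seed=0)
cols = ["population", "habitat", "n", "npl", "A", "Ar", "H_O", "H_E", "F_IS"]
print(table[cols].round(3).to_string(index=False))
print(
    "\nnpl/A/Ar shrink and heterozygosity drops from the connected marine pool"
    "\nto the long-isolated pond, while F_IS stays near zero everywhere"
    "\n(random mating holds within each population)."
)
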