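"""Bottleneck detection on a recently founded pond population.

A pond founded 50 generations ago by 20 colonists from a large marine pool
is still in its bottleneck phase: it has lost alleles faster than gene
diversity (heterozygosity excess) and its allele-size range retains gaps
(depressed Garza-Williamson M).  Both tests should flag it; the same tests
on the equilibrium marine pool should not.
"""

from msatld import (
    TPMParams,
    critical_m,
    heterozygosity_excess_test,
    m_ratio,
    preset_scenarios,
    simulate_metapopulation,
)

TPM = TPMParams(p_single=0.9, mean_multistep=3.5, mu=1.5e-4)
presets = preset_scenarios(rescale=10)

for key, pop, prebottleneck_ne in [
    ("inland_pond_recent", "pond1", 1000),
    ("marine", "marine1", 5000),
]:
    dataset, _, _ = simulate_metapopulation(presets[key], seed=41)
    p_het = heterozygosity_excess_test(dataset, pop, params=TPM, n_iter=200, seed=1)
    per_locus, m = m_ratio(dataset, pop)
    theta = 4 * prebottleneck_ne * TPM.mu
    mc = critical_m(theta, TPM, 24, len(per_locus), n_iter=2000, seed=2)
    verdict = "BOTTLENECK" if m < mc else "no bottleneck"
    print(
        f"{key:>18}: het-excess p = {p_het:.4f} | "
        f"M = {m:.3f} vs Mc(theta={theta:.2f}) = {mc:.3f} -> {verdict}"
    )

print(
    "\nM below its simulated critical value and a small Wilcoxon p jointly"
    "\nindicate a founder event; the marine pool sits at mutation-drift"
    "\nequilibrium and stays at nominal significance."
)
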