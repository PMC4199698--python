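# Methods

`msatld` analyses genome-wide linkage disequilibrium (LD) in multiallelic
microsatellite surveys of structured populations, together with the
population-genetic context such an analysis needs: diversity, F-statistics,
AMOVA, relatedness, and bottleneck tests.  This note documents the models,
estimators, numerical choices and known limitations.

## Data model

Genotypes are diploid, unphased, multiallelic; allele codes are fragment
sizes in base pairs.  The interchange format is GenePop (4- and 6-digit
dialects auto-detected); missing data follow the all-zeros convention, and a
genotype with one missing allele is treated as fully missing — the simplest
defensible contract for partially failed fragment calls.  The marker map is
a TSV of marker → (linkage group, physical position in Mb), optionally
carrying a per-marker repeat-motif length (`motif_bp`, default 4 bp), which
only the M-ratio needs.  Markers absent from the map are simply excluded
from syntenic analyses.

## LD estimation

All pairwise statistics start from the per-allele-pair coefficient
D_ij = p(A_iB_j) − p_i q_j.

**Multiallelic D′** is the allele-frequency-weighted mean of |D_ij/Dmax_ij|,
with Dmax_ij = min(p_i q_j, (1−p_i)(1−q_j)) for negative D_ij and
min(p_i(1−q_j), q_j(1−p_i)) otherwise.  Pairs where Dmax_ij = 0 (an allele
fixed against another) contribute 0, which keeps D′ in [0, 1] for every
valid frequency table.  This bound is verified by a randomized property test
over Dirichlet-distributed joint tables.

**Multiallelic r²** is implemented as
Σ_ij p_i q_j D_ij² / [p_i(1−p_i) q_j(1−q_j)].  The allele-frequency weights
are essential: without them the statistic is exactly 4× the classical
r² = D²/(p_A q_A p_B q_B) on any biallelic pair, whereas the weighted form
reduces to the classical value exactly.  Even weighted, the statistic is not
guaranteed to stay below 1 when loci carry many alleles; it is reported as
computed.

**Two-locus EM.**  Haplotype frequencies come from the standard two-locus EM
for unphased diploids.  Phase is ambiguous only for double heterozygotes;
all other genotypes contribute fixed haplotype counts.  Frequencies are
initialized at the product of the observed allele margins and iterated until
the largest absolute change is below 1e-8 (cap 1000 iterations;
non-convergence is flagged on the result, which is kept).  The observed-data
log-likelihood is recorded per iteration and is non-decreasing; margins of
the EM solution equal the observed allele frequencies to numerical
precision.  Note the product initialization is itself a fixed point on a
single double-heterozygote: with no other information the four haplotypes
stay at 0.25 each, which is the maximum-likelihood answer for that datum.

Genome-wide Bayesian phasing is deliberately **not** performed: pairwise LD
needs only two-locus haplotype frequencies, and the composite-LD route below
provides a phasing-free sensitivity check.  Missing genotypes are handled by
pairwise deletion per locus pair; nothing is imputed.

**Composite LD.**  Burrows' composite coefficient
Δ_ij = (within-gamete + between-gamete association) − 2 p_i q_j is estimated
from genotype dosages as Δ̂_ij = mean(g_Ai·g_Bj)/2 − 2 p̂_i q̂_j.  We divide
Δ̂ by 2 to put it on the per-gamete scale before substituting it for D_ij in
the D′/r² aggregations (same Dmax branches).  This normalization makes the
composite coefficients *identical* to the directly counted haplotypic D_ij
whenever the data contain no double heterozygotes (algebraically,
Δ̂ = 2·D̂ of the estimator that splits double heterozygotes 50/50), which is
the natural consistency requirement; the exact normalization used by legacy
programs is not documented and may differ by this factor.

**Scans, bins, decay.**  Syntenic scans compute one record per same-LG
marker pair with both loci polymorphic in the analysis unit.  Units are
populations, habitat labels (member populations' genotypes pooled before
estimation — the "combined" convention), or explicit population lists.
An `exclude_rare` flag drops alleles below 5% frequency by setting genotypes
that carry them to missing at that locus before estimation.  Distance
binning uses right-closed Mb bins (0–5], (5–10], (10–15], (15–20], >20 with
mean D′ and the estimation error SD/√n_pairs per bin, plus an overall row
that is the pair-weighted mean of all syntenic records.  LD decay is an OLS
fit of D′ on ln(distance); the half-length, exp((0.5 − intercept)/slope), is
reported only when the slope is negative.  Constant-response and
single-distance degenerate inputs return slope 0, R² 0, p 1 with a flag.

## Diversity statistics

Expected heterozygosity uses Nei's unbiased correction (2n/(2n−1))(1−Σp²) —
at n = 24 the correction is ~2%.  Multilocus values are unweighted means
over loci with data, monomorphic loci included (they contribute 0).  F_IS is
the Weir–Cockerham single-population f, combined over alleles and loci as a
ratio of summed variance components, with a percentile bootstrap over loci
(default 1000 resamples) for the 95% CI.  Allelic richness and private
allelic richness are Kalinowski-style rarefaction at the gene-copy level
with one global subsample size g (default: the smallest per-locus
non-missing gene count over populations); hierarchical region-level
rarefaction is not implemented.  Both rarefaction estimators are verified
against exhaustive subset enumeration on small inputs.  The rare-allele
proportion is the fraction of observed distinct alleles below 5% frequency.

## Population structure

Pairwise F_ST is Weir & Cockerham's θ (ratio of summed variance components
over shared polymorphic loci); significance comes from permuting individuals
between the two populations with the (1 + exceedances)/(n_perm + 1)
convention.  AMOVA is three-level (among groups / among populations within
groups / within populations) on the allele-identity distance (0/1), the
default for genotypic microsatellite data; within-unit sums of squares
reduce to (n² − Σc_a²)/(2n) from allele counts, variance components use the
standard unequal-size coefficients, and components are summed over loci.
Components can legitimately be negative; percentages always sum to 100.
Permutation schemes per level: whole populations among groups (σ_a),
individuals among populations within groups (σ_b), and individuals among
all populations for the overall differentiation (reported as p_c).
Relatedness is Queller & Goodnight's estimator, ratio-of-sums over loci,
averaged over the two reference orderings, with reference allele frequencies
computed excluding the focal pair.

## Bottleneck tests

**Heterozygosity excess.**  After a bottleneck, allele count drops faster
than gene diversity, so observed H_E exceeds the equilibrium expectation
given the observed allele count k.  The null is built by coalescent
simulation under the two-phase mutation model (TPM; single-step with
probability 0.9 by default, otherwise a jump of 1 + Geometric repeat units
with mean 3.5).  Two calibration-critical choices differ from the classic
recipe, both validated by simulation (p uniform under the equilibrium null,
KS test):

1. *Shared θ.*  One mutation parameter per population is estimated by
   matching the mean simulated allele count (among polymorphic replicates)
   to the mean observed allele count over polymorphic loci; every locus is
   then conditioned on its own k at that shared θ.  Tuning θ per locus to
   that locus's k biases the null: E[H | k] increases with θ, so low-k loci
   receive an equilibrium distribution that is too low and the test fires at
   ~4× the nominal rate.  (Per-locus tuning remains available via
   `shared_theta=False`.)
2. *Quantile statistic.*  The per-locus quantity ranked by the one-tailed
   Wilcoxon signed-rank test is the centered conditional quantile of the
   observed H_E within the equilibrium draws, not the standardized
   difference (H_E − mean H_eq)/SD.  The conditional H distribution is
   left-skewed, and a signed-rank test of a skewed zero-mean variable is
   anticonservative; the quantile is symmetric under the null by
   construction.  The standardized differences are still reported in the
   per-locus detail table.

Conditioning uses rejection sampling (accept replicates whose simulated k
equals the observed k); if acceptance falls below 1% the θ bracket is
widened by redrawing θ per batch.  Loci sharing (sample size, k) share null
draws.  The test requires ≥ 4 polymorphic loci.

**M-ratio.**  Per polymorphic locus, M = k/r with r = (max − min)/motif + 1
lattice states spanned by the observed size range (endpoints included);
off-lattice sizes are snapped to the nearest state with a warning, so M ≤ 1
always.  The multilocus M is the mean over polymorphic loci.  The critical
value M_c is the 5th percentile (lower tie-break) of multilocus M over
equilibrium coalescent replicates at a chosen pre-bottleneck θ = 4Ne·μ
(defaults: Ne grid 1000/5000/10000 for marine and coastal populations,
100/500/1000 for inland ones; μ = 1.5e-4), with the same number of loci and
individuals as observed; M < M_c flags a bottleneck.

A property of the model worth knowing: at *low* θ, equilibrium per-locus M
is *high* (~0.94 at θ = 0.06) because the rare polymorphic loci mostly carry
two adjacent alleles, and it decreases with θ (~0.79 at θ = 6) as mutation
spreads alleles over more lattice states.  Consequently a small isolated
population that has reached its own equilibrium shows no M-ratio signal —
the test detects the *transient* after a contraction, not small size per se.
The coalescent sampler is vectorized over replicates (array-based merge
events, Poisson branch mutations, segment-summed TPM steps), so 10⁴
replicate loci simulate in seconds.

## Statistical comparisons

Mann–Whitney U uses the tie-corrected normal approximation and reports
(U, Z, two-sided p); Kruskal–Wallis is the tie-corrected H with a χ²
reference.  For two tie-free groups H = Z² exactly and the p-values agree.
The ANCOVA of D′ on habitat, population-within-habitat and marker distance
uses sequential sums of squares with the covariate entered first; the
habitat F-statistic is tested against the population-within-habitat mean
square — the classical expected-mean-squares treatment of a nested design,
which gives the same F as a mixed model in balanced designs without opaque
fitting machinery — and populations are tested against the residual.  With
one population per habitat the habitat test is confounded and flagged
untestable.  The distance covariate is raw Mb by default (ln-distance by
flag).  Bonferroni adjustment is min(1, m·p), with the α/m threshold form
also exposed.

## Synthetic data generator

The generator is a diploid Wright–Fisher forward simulation with
recombination and TPM mutation, emulating the survey design the analysis
modules target: 109 microsatellites on 20 linkage groups (2–13 markers per
group, spacings 0.001–11.5 Mb, mean ≈ 2.7 Mb; the layout is deterministic),
24 sampled diploids per population, and a habitat-structured demography.

*Initialization.*  The ancestral pool starts at exact mutation-drift
equilibrium from a coalescent sample (loci independent; pools larger than
300 diploids are initialized from a 600-copy sample expanded multinomially)
and runs forward for a short burn-in (default 200 generations) so that
within-linkage-group LD reaches its drift–recombination quasi-equilibrium —
the LD relaxation time, ~1/(2r + 1/2N), is far shorter than the diversity
timescale, which the coalescent init already satisfies.

*Dynamics.*  Each generation: random diploid parents (selfing allowed),
gametes formed with recombination probability min(0.5, rate·Mb) between
adjacent syntenic markers (default 1 cM/Mb; each linkage group starts with
an independent random phase), symmetric TPM mutation at μ = 1.5e-4, repeat
counts reflected into [5, 60].  Daughter populations are founded from the
pool at stated times with stated founder counts and may receive migrants
(each individual replaced by a pool individual with probability m per
generation).  A founding time of 0 means the population *is* the pool (used
for the marine condition).

*Presets.*  marine: the connected Ne = 5000 pool.  coastal: founded 500
generations ago by 200 colonists, Ne = 1000, continuing migration m = 0.01
(4Nm ≈ 40, hence marine-like diversity and LD).  inland_lake: 50 colonists,
Ne = 500, isolated 2000 generations.  inland_pond: 20 colonists, Ne = 100,
isolated 2000 generations — at 10 coalescent units of isolation this
population sits at its own low-θ equilibrium (H_E ≈ 0.06–0.12, most loci
monomorphic), matching the most depauperate natural isolates.
inland_pond_recent: the same founder event sampled 50 generations after
founding, i.e. in the bottleneck phase where heterozygosity excess and the
depressed M-ratio are present; bottleneck power analyses use this variant,
since the equilibrated pond by construction carries no transient signal (and
correspondingly the most equilibrated natural isolates are where M-ratio
tests come up empty).

*Rescaling.*  `DemographicScenario.rescaled(c)` divides Ne, founder counts,
founding times and burn-in by c and multiplies μ, m and the recombination
rate by c, preserving 4Neμ, 4Nem and 4Ner.  Rescaled Ne is floored at the
24-individual sample size, so for very small populations large c distorts θ
upward (the pond at c = 10 runs at θ ≈ 0.14 instead of 0.06); orderings and
power conclusions are insensitive to this, but absolute pond diversity is
slightly inflated at high rescale factors.  Validation and the acceptance
study run at c = 10; the tests' problem sizes (50 bottleneck replicates, 10
habitat replicate sets, 100–120 calibration replicates) are chosen so the
whole validation suite completes in minutes on one core.

*Truth records.*  `SimTruth` carries the sampled chromosomes' realized
allele frequencies and two-locus haplotype frequencies for every syntenic
pair, so EM estimates can be checked against phase-known truth on the exact
sample the estimator sees.

*What the generator does not emulate.*  Genotyping artifacts (allele
dropout, stutter, size binning errors), mutation-rate variation across loci,
selection, sex-specific recombination, spatial/river geometry, and
recombination-rate heterogeneity along chromosomes.  Passing tests therefore
demonstrate estimator correctness and qualitative demographic-pattern
recovery, not robustness to real-data artifacts.

## Numerical and API conventions

Permutation p-values use the +1 correction, so p ∈ (0, 1] and the smallest
attainable value is 1/(n_perm + 1).  All randomness is NumPy
`default_rng`/`SeedSequence`; fixed seeds give bit-identical outputs,
including exported files.  The pipeline derives independent substreams per
stage from the single run seed, so disabling one stage never changes
another's numbers.  Monomorphic loci: excluded from LD pairs and from
M-ratio; contribute 0 to multilocus H_E/H_O; excluded from the
heterozygosity-excess ranking.  Degenerate inputs (no shared polymorphic
locus, < 4 polymorphic loci, zero-variance correlations, confounded ANCOVA)
raise typed errors or set documented flags rather than returning silent
NaNs.

## Known limitations

- The multiallelic D′ of a finite sample is biased upward, increasingly so
  with allele count; at n = 24 even unlinked loci in a large population show
  pooled D′ ≈ 0.4.  Comparisons between units of equal sample size remain
  meaningful; absolute D′ values should not be read as recombination
  estimates.  (Recombination rate is not modelled in the estimators at all.)
- The composite-LD normalization is a documented choice (Δ/2), not asserted
  identical to legacy implementations.
- Rarefaction uses a single global g; region-hierarchical richness is out of
  scope.
- The heterozygosity-excess null assumes a single mutation model and rate
  across loci; with strong across-locus rate variation the shared-θ
  conditioning is misspecified (per-locus mode exists but is
  anticonservative at equilibrium).
- AMOVA treats genotypic data at the allele level with three levels; a
  four-level design with a within-individual component is not implemented.
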