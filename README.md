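# msatld

Genome-wide linkage disequilibrium and population-genetic analysis of
multiallelic microsatellite data.

## The problem

Surveys of wild populations genotyped at ~100 microsatellites across a
sparse physical map ask a recurring set of questions: how much genetic
diversity does each population hold, how differentiated are they, have they
been through bottlenecks, and — the centrepiece here — how strong is
linkage disequilibrium (LD) between syntenic markers, and how does it differ
between demographic settings (large connected marine populations vs recently
founded coastal freshwater ones vs small, long-isolated inland lakes and
ponds)?  `msatld` implements that whole workflow for unphased diploid
multiallelic data, plus a forward-time simulator of the habitat-structured
demography so every stage can be validated without any external data.

## The statistics at its core

For two loci with alleles A_i (frequencies p_i) and B_j (frequencies q_j)
and haplotype frequencies p(A_iB_j), let D_ij = p(A_iB_j) − p_i q_j.  The
package computes

- multiallelic **D′** = Σ_ij p_i q_j |D_ij / Dmax_ij|, with the usual
  min(...) branches for Dmax_ij, bounded in [0, 1];
- multiallelic **r²** = Σ_ij p_i q_j D_ij² / [p_i(1−p_i) q_j(1−q_j)], which
  reduces to the classical D²/(p_A q_A p_B q_B) for biallelic loci;

with haplotype frequencies estimated from unphased genotypes by a two-locus
EM algorithm, or phase-free via Burrows' composite disequilibrium.  Around
this sit: Nei's unbiased H_E, Weir–Cockerham F_IS and pairwise F_ST with
permutation tests, rarefied (private) allelic richness, three-level AMOVA,
Queller–Goodnight relatedness, the heterozygosity-excess bottleneck test
under a two-phase mutation model, and the Garza–Williamson M-ratio with
simulated critical values.  Details and derivations: `docs/methods.md`.

## Worked example

`examples/01_simulate_and_diversity.py` simulates one population per habitat
condition from a shared ancestral pool (Ne-rescaled ×25 for speed) and
prints the standard variability table:

```
population habitat  n  npl   A    Ar   H_O   H_E   F_IS
   marine1  marine 24  109 549 5.037 0.651 0.648 -0.004
  coastal1    lake 24  109 570 5.229 0.632 0.632  0.000
     lake1    lake 24   91 254 2.330 0.307 0.301 -0.021
     pond1    pond 24   91 256 2.349 0.287 0.281 -0.023
```

Reading it: the connected marine pool and the migration-coupled coastal
population keep all 109 loci polymorphic with H_E ≈ 0.65, while the isolated
lake and pond have lost alleles to founder events and drift (H_E ≈ 0.3,
~17% of loci monomorphic); F_IS ≈ 0 everywhere, so mating is random within
populations.  `examples/02_ld_scan_and_decay.py` then scans all syntenic
pairs in an inland lake and prints, among other lines,

```
     overall 0.718  0.024      211
decay fit: D' = 0.726 -0.0050 ln(d); R^2 = 0.0003 (p = 0.818)
```

— high D′ at every distance with an essentially flat decay (R² < 0.01),
the signature of drift-dominated LD on a sparse map.  The other examples
cover population structure (F_ST/AMOVA/relatedness), bottleneck detection,
and the habitat-level LD comparison (pond > lake > marine, coastal ≈
marine).

There is also a thin CLI for batch runs over GenePop inputs or simulated
presets:

```bash
msatld all --preset survey --rescale 25 --seed 1 --out-dir out/
msatld ld --genepop data.gen --marker-map map.tsv --habitat-table hab.tsv \
          --out-dir out/ --exclude-rare
```

Every report is TSV with the tool version, seed and config echoed in
comment headers, plus a checksum manifest.

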