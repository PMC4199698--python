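"""Per-population genetic-variability statistics.

Observed and expected heterozygosity, the Weir-Cockerham inbreeding
coefficient F_IS with a bootstrap-over-loci confidence interval, rarefied
allelic and private allelic richness (Kalinowski's estimators), and the
proportion of rare alleles.  Expected heterozygosity uses Nei's unbiased
correction 2n/(2n-1), which matters at the sample sizes (n = 24) typical of
microsatellite surveys.  Multilocus statistics are unweighted means over loci
with data, monomorphic loci included (they contribute 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genodata import MISSING, GenotypeDataset, Population, allele_counts


class UndefinedStatistic(ValueError):
    """Raised when a statistic is undefined for the given data."""


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def observed_heterozygosity(dataset: GenotypeDataset, population: str):
    """Per-locus fraction of heterozygous individuals; multilocus mean.

    Returns ``(per_locus, multilocus)``; loci with no data are NaN and are
    excluded from the multilocus mean.
    """
    pop = dataset.population(population)
    g = pop.genotypes
    ok = ~pop.missing_mask()
    het = (g[:, :, 0] != g[:, :, 1]) & ok
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(n > 0, het.sum(axis=0) / n, np.nan)
    return per_locus, float(np.nanmean(per_locus))


def expected_heterozygosity(dataset: GenotypeDataset, population: str):
    """Nei's unbiased gene diversity (2n/(2n-1)) * (1 - sum p_i^2) per locus."""
    pop = dataset.population(population)
    per_locus = np.full(dataset.n_loci, np.nan)
    for l in range(dataset.n_loci):
        _, counts = allele_counts(pop, l)
        total = counts.sum()
        if total == 0:
            continue
        p = counts / total
        if total < 2:
            per_locus[l] = 0.0
            continue
        per_locus[l] = (total / (total - 1)) * (1.0 - np.sum(p**2))
    return per_locus, float(np.nanmean(per_locus))


# ---------------------------------------------------------------------------
# F_IS (Weir & Cockerham single-population f)
# ---------------------------------------------------------------------------

def _fis_components(pop: Population, locus_idx: int):
    """Per-allele variance components (b, c) of Weir & Cockerham for r = 1.

    f = 1 - sum(c) / sum(b + c), summed over alleles and loci.
    """
    g = pop.genotypes[:, locus_idx, :]
    ok = (g != MISSING).all(axis=1)
    g = g[ok]
    n = g.shape[0]
    if n < 2:
        return np.array([]), np.array([])
    alleles = np.unique(g)
    b = np.empty(len(alleles))
    c = np.empty(len(alleles))
    for k, a in enumerate(alleles):
        dose = (g == a).sum(axis=1)
        p = dose.mean() / 2.0
        hbar = np.mean(dose == 1)
        b[k] = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) * hbar / (4.0 * n))
        c[k] = hbar / 2.0
    return b, c


def fis_with_ci(
    dataset: GenotypeDataset,
    population: str,
    n_boot: int = 1000,
    seed: int | None = None,
):
    """Multilocus Weir-Cockerham f with a percentile bootstrap-over-loci 95% CI.

    Returns ``(f, (lo, hi))``.  Requires at least two polymorphic loci.
    """
    pop = dataset.population(population)
    per_locus = []
    for l in range(dataset.n_loci):
        b, c = _fis_components(pop, l)
        if b.size and (b + c).sum() > 0:
            per_locus.append((b.sum(), c.sum()))
    if len(per_locus) < 2:
        raise UndefinedStatistic(
            f"F_IS undefined for {population!r}: fewer than 2 polymorphic loci"
        )
    bc = np.asarray(per_locus)  # columns: sum(b), sum(c) per locus
    f_obs = 1.0 - bc[:, 1].sum() / (bc[:, 0] + bc[:, 1]).sum()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(bc), size=(n_boot, len(bc)))
    bsum = bc[idx, 0].sum(axis=1)
    csum = bc[idx, 1].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_boot = 1.0 - csum / (bsum + csum)
    f_boot = f_boot[np.isfinite(f_boot)]
    lo, hi = np.percentile(f_boot, [2.5, 97.5])
    return float(f_obs), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _prob_absent(N, Na, g):
    """P(allele with Na of N copies absent from a subsample of g copies)."""
    if N - Na < g:
        return 0.0
    return float(np.exp(_log_comb(N - Na, g) - _log_comb(N, g)))


def default_rarefaction_size(dataset: GenotypeDataset) -> int:
    """Smallest per-locus non-missing gene count across populations and loci."""
    counts = []
    for pop in dataset.populations:
        n_ok = (~pop.missing_mask()).sum(axis=0) * 2
        counts.append(n_ok[n_ok > 0].min() if (n_ok > 0).any() else None)
    counts = [c for c in counts if c is not None]
    if not counts:
        raise UndefinedStatistic("no data for rarefaction")
    return int(min(counts))


def allelic_richness(dataset: GenotypeDataset, g: int | None = None) -> dict[str, float]:
    """Rarefied allelic richness per population at gene-copy size ``g``.

    Per locus Ar = sum over alleles of 1 - C(N - Na, g)/C(N, g); the
    population value is the mean over loci with at least g copies.
    """
    if g is None:
        g = default_rarefaction_size(dataset)
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    out = {}
    for pop in dataset.populations:
        per_locus = []
        for l in range(dataset.n_loci):
            alleles, counts = allele_counts(pop, l)
            N = int(counts.sum())
            if N < g:
                continue
            ar = sum(1.0 - _prob_absent(N, int(na), g) for na in counts)
            per_locus.append(ar)
        out[pop.name] = float(np.mean(per_locus)) if per_locus else float("nan")
    return out


def private_allelic_richness(
    dataset: GenotypeDataset, g: int | None = None
) -> dict[str, float]:
    """Kalinowski's rarefied private allelic richness per population.

    An allele contributes P(present in the focal rarefied sample) times the
    product over all other populations of P(absent from their rarefied
    samples).
    """
    if len(dataset.populations) < 2:
        raise UndefinedStatistic("private allelic richness needs >= 2 populations")
    if g is None:
        g = default_rarefaction_size(dataset)
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    counts_by_pop = [
        [allele_counts(pop, l) for l in range(dataset.n_loci)]
        for pop in dataset.populations
    ]
    out = {}
    for i, focal in enumerate(dataset.populations):
        per_locus = []
        for l in range(dataset.n_loci):
            alleles_f, counts_f = counts_by_pop[i][l]
            N_f = int(counts_f.sum())
            if N_f < g:
                continue
            others = []
            feasible = True
            for j in range(len(dataset.populations)):
                if j == i:
                    continue
                a_o, c_o = counts_by_pop[j][l]
                N_o = int(c_o.sum())
                if N_o < g:
                    feasible = False
                    break
                others.append((dict(zip(a_o.tolist(), c_o.tolist())), N_o))
            if not feasible:
                continue
            pr = 0.0
            for a, na in zip(alleles_f, counts_f):
                term = 1.0 - _prob_absent(N_f, int(na), g)
                for lookup, N_o in others:
                    term *= _prob_absent(N_o, lookup.get(int(a), 0), g)
                pr += term
            per_locus.append(pr)
        out[focal.name] = float(np.mean(per_locus)) if per_locus else float("nan")
    return out


# ---------------------------------------------------------------------------
# Rare alleles and summary table
# ---------------------------------------------------------------------------

def rare_allele_proportion(
    dataset: GenotypeDataset, population: str, threshold: float = 0.05
) -> float:
    """Fraction of observed distinct alleles with frequency below ``threshold``."""
    pop = dataset.population(population)
    n_rare = 0
    n_total = 0
    for l in range(dataset.n_loci):
        _, counts = allele_counts(pop, l)
        total = counts.sum()
        if total == 0:
            continue
        freqs = counts / total
        n_total += len(freqs)
        n_rare += int((freqs < threshold).sum())
    if n_total == 0:
        raise UndefinedStatistic(f"population {population!r} has no alleles")
    return n_rare / n_total


def diversity_table(
    dataset: GenotypeDataset,
    g: int | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Summary table: one row per population with the standard variability
    statistics (n, npl, A, Ar, Pr, H_O, H_E, F_IS and its 95% CI, rare-allele
    proportion)."""
    ar = allelic_richness(dataset, g=g)
    pr = (
        private_allelic_richness(dataset, g=g)
        if len(dataset.populations) >= 2
        else {p.name: float("nan") for p in dataset.populations}
    )
    rows = []
    for pop in dataset.populations:
        npl = 0
        n_alleles = 0
        for l in range(dataset.n_loci):
            alleles, _ = allele_counts(pop, l)
            n_alleles += len(alleles)
            if len(alleles) > 1:
                npl += 1
        _, ho = observed_heterozygosity(dataset, pop.name)
        _, he = expected_heterozygosity(dataset, pop.name)
        try:
            fis, (lo, hi) = fis_with_ci(dataset, pop.name, n_boot=n_boot, seed=seed)
        except UndefinedStatistic:
            fis, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append(
            {
                "population": pop.name,
                "habitat": pop.habitat,
                "coastal": int(pop.coastal),
                "n": pop.n_individuals,
                "npl": npl,
                "A": n_alleles,
                "Ar": ar[pop.name],
                "Pr": pr[pop.name],
                "H_O": ho,
                "H_E": he,
                "F_IS": fis,
                "CI_low": lo,
                "CI_high": hi,
                "rare_allele_proportion": rare_allele_proportion(dataset, pop.name),
            }
        )
    return pd.DataFrame(rows)
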