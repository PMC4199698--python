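"""Multiallelic linkage disequilibrium from unphased diploid genotypes.

Two gametic LD summaries are computed for a pair of loci A (alleles A_i,
frequencies p_i) and B (alleles B_j, frequencies q_j) from the per-allele-pair
coefficients D_ij = p(A_iB_j) - p_i q_j:

* multiallelic D' = sum_ij p_i q_j |D_ij / Dmax_ij|, where
  Dmax_ij = min(p_i q_j, (1-p_i)(1-q_j))        if D_ij < 0
  Dmax_ij = min(p_i (1-q_j), q_j (1-p_i))       if D_ij >= 0,
  bounded in [0, 1];
* multiallelic r^2 = sum_ij p_i q_j D_ij^2 / [p_i(1-p_i) q_j(1-q_j)].  The
  allele-frequency weights make the statistic reduce exactly to the
  classical r^2 = D^2/(p_A q_A p_B q_B) for biallelic loci (the unweighted
  sum would be 4x the classical value there); it is still not guaranteed
  to stay below 1 for loci with many alleles (see docs/methods.md).

Haplotype frequencies are estimated from unphased genotypes by a two-locus EM
algorithm; a phasing-free composite-disequilibrium route (Burrows' Delta,
halved to the gamete scale) is provided as a sensitivity check.  Scans over
syntenic marker pairs, distance binning, log-distance decay regression, and
the D'/r^2 correlation complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeDataset, MarkerMap, Population


class MonomorphicLocusError(ValueError):
    """LD is undefined when either locus is monomorphic in the analysis unit."""


@dataclass
class HaplotypeFreqTable:
    """Joint two-locus haplotype frequency matrix with allele margins."""

    locusA: str
    locusB: str
    alleles_a: np.ndarray  # sorted allele codes at locus A
    alleles_b: np.ndarray
    freq: np.ndarray  # (k, l) haplotype frequencies, sums to 1
    n_chromosomes: int
    source: str = "EM"  # EM | direct | simulated-truth
    converged: bool = True
    n_iter: int = 0
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def margin_a(self) -> np.ndarray:
        return self.freq.sum(axis=1)

    @property
    def margin_b(self) -> np.ndarray:
        return self.freq.sum(axis=0)


# ---------------------------------------------------------------------------
# Two-locus genotype extraction
# ---------------------------------------------------------------------------

def _pairwise_complete(pop_genotypes: np.ndarray, ia: int, ib: int):
    """Genotypes at two loci for individuals non-missing at both (n, 2, 2)."""
    ga = pop_genotypes[:, ia, :]
    gb = pop_genotypes[:, ib, :]
    ok = (ga != MISSING).all(axis=1) & (gb != MISSING).all(axis=1)
    return ga[ok], gb[ok]


def _index_alleles(ga: np.ndarray, gb: np.ndarray):
    alleles_a, a_idx = np.unique(ga, return_inverse=True)
    alleles_b, b_idx = np.unique(gb, return_inverse=True)
    return (
        alleles_a,
        a_idx.reshape(ga.shape),
        alleles_b,
        b_idx.reshape(gb.shape),
    )


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimation
# ---------------------------------------------------------------------------

def em_haplotype_frequencies(
    dataset_or_genotypes,
    population: str | None = None,
    locusA: str | None = None,
    locusB: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeFreqTable:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    Phase is ambiguous only for double heterozygotes; all other genotypes
    contribute fixed haplotype counts.  Frequencies are initialized at the
    product of the observed allele margins and iterated until the largest
    absolute frequency change falls below ``tol``.  Individuals missing either
    locus are excluded pairwise.

    Accepts either ``(dataset, population, locusA, locusB)`` or a raw
    ``(n, 2, 2)``-style pair via ``genotype_pair=(ga, gb)`` passed positionally
    as ``em_haplotype_frequencies((ga, gb))``.
    """
    if isinstance(dataset_or_genotypes, GenotypeDataset):
        ds = dataset_or_genotypes
        pop = ds.population(population)
        ga, gb = _pairwise_complete(
            pop.genotypes, ds.locus_index(locusA), ds.locus_index(locusB)
        )
        name_a, name_b = locusA, locusB
    else:
        ga, gb = dataset_or_genotypes
        ga, gb = np.asarray(ga), np.asarray(gb)
        ok = (ga != MISSING).all(axis=1) & (gb != MISSING).all(axis=1)
        ga, gb = ga[ok], gb[ok]
        name_a, name_b = locusA or "A", locusB or "B"

    n = ga.shape[0]
    if n == 0:
        raise ValueError("no individuals with data at both loci")
    alleles_a, ai, alleles_b, bi = _index_alleles(ga, gb)
    k, l = len(alleles_a), len(alleles_b)
    n_chrom = 2 * n

    # Fixed haplotype counts from phase-unambiguous individuals; ambiguous
    # double heterozygotes keep their two possible resolutions.
    fixed = np.zeros((k, l))
    amb = []  # rows (a1, b1, a2, b2): resolution 1 = (a1,b1)+(a2,b2)
    for ind in range(n):
        a1, a2 = ai[ind]
        b1, b2 = bi[ind]
        if a1 != a2 and b1 != b2:
            amb.append((a1, b1, a2, b2))
        else:
            fixed[a1, b1] += 1
            fixed[a2, b2] += 1
    amb = np.asarray(amb, dtype=int)

    pa = np.bincount(ai.ravel(), minlength=k) / n_chrom
    pb = np.bincount(bi.ravel(), minlength=l) / n_chrom
    h = np.outer(pa, pb)
    h /= h.sum()

    loglik = []
    n_done = 0
    converged = True
    if amb.size:
        a1, b1, a2, b2 = amb.T
        for n_done in range(1, max_iter + 1):
            w1 = h[a1, b1] * h[a2, b2]
            w2 = h[a1, b2] * h[a2, b1]
            tot = w1 + w2
            safe = tot > 0
            post = np.divide(w1, tot, out=np.full_like(tot, 0.5), where=safe)
            counts = fixed.copy()
            np.add.at(counts, (a1, b1), post)
            np.add.at(counts, (a2, b2), post)
            np.add.at(counts, (a1, b2), 1.0 - post)
            np.add.at(counts, (a2, b1), 1.0 - post)
            h_new = counts / n_chrom
            # observed-data log-likelihood at the current h (up to genotype
            # multiplicity constants): unambiguous haplotype counts plus the
            # summed phase weights of the double heterozygotes
            ll = float(
                np.sum(fixed[fixed > 0] * np.log(h[fixed > 0]))
                + (np.log(tot[safe]).sum() if safe.any() else 0.0)
            )
            loglik.append(ll)
            delta = np.abs(h_new - h).max()
            h = h_new
            if delta < tol:
                break
        else:
            converged = False
    else:
        h = fixed / n_chrom

    return HaplotypeFreqTable(
        locusA=name_a,
        locusB=name_b,
        alleles_a=alleles_a,
        alleles_b=alleles_b,
        freq=h,
        n_chromosomes=n_chrom,
        source="EM" if amb.size else "direct",
        converged=converged,
        n_iter=n_done,
        loglik_history=np.asarray(loglik),
    )


def haplotype_table_from_freqs(freq, alleles_a=None, alleles_b=None, n_chromosomes=0,
                               source="simulated-truth") -> HaplotypeFreqTable:
    """Wrap a raw joint-frequency matrix (e.g. simulation truth) as a table."""
    freq = np.asarray(freq, dtype=float)
    k, l = freq.shape
    if alleles_a is None:
        alleles_a = np.arange(k)
    if alleles_b is None:
        alleles_b = np.arange(l)
    return HaplotypeFreqTable(
        locusA="A", locusB="B",
        alleles_a=np.asarray(alleles_a), alleles_b=np.asarray(alleles_b),
        freq=freq, n_chromosomes=n_chromosomes, source=source,
    )


# ---------------------------------------------------------------------------
# D' and r^2 aggregation
# ---------------------------------------------------------------------------

def _check_polymorphic(pa, pb):
    if (pa > 0).sum() < 2 or (pb > 0).sum() < 2:
        raise MonomorphicLocusError("both loci must carry >= 2 alleles")


def _dprime_from_d(D: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> float:
    _check_polymorphic(pa, pb)
    PA, PB = np.meshgrid(pa, pb, indexing="ij")
    dmax_neg = np.minimum(PA * PB, (1 - PA) * (1 - PB))
    dmax_pos = np.minimum(PA * (1 - PB), PB * (1 - PA))
    dmax = np.where(D < 0, dmax_neg, dmax_pos)
    # fixed-against-fixed terms (Dmax = 0) contribute 0
    ratio = np.abs(np.divide(D, dmax, out=np.zeros_like(D), where=dmax > 0))
    return float(np.sum(PA * PB * ratio))


def _r2_from_d(D: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> float:
    _check_polymorphic(pa, pb)
    PA, PB = np.meshgrid(pa, pb, indexing="ij")
    denom = PA * (1 - PA) * PB * (1 - PB)
    terms = np.divide(
        PA * PB * D**2, denom, out=np.zeros_like(D), where=denom > 0
    )
    return float(np.sum(terms))


def dprime_multiallelic(h: HaplotypeFreqTable) -> float:
    """Allele-frequency-weighted multiallelic D' in [0, 1]."""
    pa, pb = h.margin_a, h.margin_b
    D = h.freq - np.outer(pa, pb)
    return _dprime_from_d(D, pa, pb)


def r2_multiallelic(h: HaplotypeFreqTable) -> float:
    """Multiallelic r^2 (allele-frequency-weighted sum over allele pairs,
    >= 0; equals D^2/(p_A q_A p_B q_B) for biallelic loci)."""
    pa, pb = h.margin_a, h.margin_b
    D = h.freq - np.outer(pa, pb)
    return _r2_from_d(D, pa, pb)


# ---------------------------------------------------------------------------
# Composite LD (phasing-free)
# ---------------------------------------------------------------------------

def composite_delta(ga: np.ndarray, gb: np.ndarray):
    """Burrows' composite disequilibrium from unphased genotype counts.

    For allele pair (i, j), Delta_ij = mean(g_Ai * g_Bj)/2 - 2 p_i q_j where
    g_Ai is the per-individual dose (0/1/2) of allele A_i.  Delta combines the
    within- and between-gamete associations.  Returned per-pair coefficients
    are Delta_ij / 2, the gamete-scale analogue of D_ij: on data with no
    double heterozygotes this equals the directly counted haplotypic D_ij.
    """
    alleles_a, ai, alleles_b, bi = _index_alleles(ga, gb)
    k, l = len(alleles_a), len(alleles_b)
    n = ga.shape[0]
    dose_a = np.zeros((n, k))
    dose_b = np.zeros((n, l))
    for c in range(2):
        np.add.at(dose_a, (np.arange(n), ai[:, c]), 1.0)
        np.add.at(dose_b, (np.arange(n), bi[:, c]), 1.0)
    pa = dose_a.mean(axis=0) / 2.0
    pb = dose_b.mean(axis=0) / 2.0
    delta = (dose_a.T @ dose_b) / (2.0 * n) - 2.0 * np.outer(pa, pb)
    return alleles_a, alleles_b, pa, pb, delta / 2.0


def composite_ld(
    dataset: GenotypeDataset,
    population: str,
    locusA: str,
    locusB: str,
) -> tuple[float, float]:
    """Composite D' and r^2 from unphased genotypes (no haplotype inference).

    The halved Burrows Delta_ij replaces the haplotypic D_ij in the same
    D' / r^2 aggregation formulas, normalized by the same Dmax branches.
    """
    ds = dataset
    pop = ds.population(population)
    ga, gb = _pairwise_complete(
        pop.genotypes, ds.locus_index(locusA), ds.locus_index(locusB)
    )
    if ga.shape[0] == 0:
        raise ValueError("no individuals with data at both loci")
    _, _, pa, pb, d_comp = composite_delta(ga, gb)
    return _dprime_from_d(d_comp, pa, pb), _r2_from_d(d_comp, pa, pb)


# ---------------------------------------------------------------------------
# Syntenic scans
# ---------------------------------------------------------------------------

def _mask_rare_alleles(genotypes: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Set genotypes carrying a rare allele (pooled frequency < threshold) to
    missing at that locus; remaining data are renormalized implicitly."""
    g = genotypes.copy()
    n_loci = g.shape[1]
    for l in range(n_loci):
        col = g[:, l, :]
        copies = col[col != MISSING]
        if copies.size == 0:
            continue
        alleles, counts = np.unique(copies, return_counts=True)
        rare = set(alleles[counts / copies.size < threshold].tolist())
        if not rare:
            continue
        drop = np.isin(col, list(rare)).any(axis=1)
        g[drop, l, :] = MISSING
    return g


def _pooled_genotypes(
    dataset: GenotypeDataset, unit: str, members: list[str] | None = None
) -> np.ndarray:
    """Genotype array for a population name, a habitat label (member
    populations pooled), or an explicit list of population names."""
    if members is not None:
        return np.concatenate(
            [dataset.population(m).genotypes for m in members], axis=0
        )
    names = dataset.population_names
    if unit in names:
        return dataset.population(unit).genotypes
    pooled = [p.genotypes for p in dataset.populations if p.habitat == unit]
    if not pooled:
        raise KeyError(f"{unit!r} is neither a population nor a habitat in dataset")
    return np.concatenate(pooled, axis=0)


def syntenic_ld_scan(
    dataset: GenotypeDataset,
    marker_map: MarkerMap,
    unit: str,
    exclude_rare: bool = False,
    measure_source: str = "EM",
    rare_threshold: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 1000,
    members: list[str] | None = None,
) -> pd.DataFrame:
    """D'/r^2 for all syntenic marker pairs in one population or habitat.

    ``unit`` may be a population name or a habitat label, in which case the
    member populations' genotypes are pooled ("combined") before estimation.
    ``measure_source`` selects EM haplotype frequencies or the composite
    (phasing-free) route for the headline dprime/r2 columns; both composite
    columns are always reported.  Pairs with a monomorphic locus in the unit
    are omitted.  ``members`` names an explicit set of populations to pool
    under the label ``unit`` (overriding name/habitat lookup).
    """
    genotypes = _pooled_genotypes(dataset, unit, members=members)
    if exclude_rare:
        genotypes = _mask_rare_alleles(genotypes, rare_threshold)
    pairs = marker_map.syntenic_pairs(dataset.loci)
    records = []
    for row in pairs.itertuples(index=False):
        ia = dataset.locus_index(row.locusA)
        ib = dataset.locus_index(row.locusB)
        ga, gb = _pairwise_complete(genotypes, ia, ib)
        if ga.shape[0] == 0:
            continue
        try:
            if measure_source == "EM":
                h = em_haplotype_frequencies(
                    (ga, gb), locusA=row.locusA, locusB=row.locusB,
                    tol=tol, max_iter=max_iter,
                )
                dp = dprime_multiallelic(h)
                r2 = r2_multiallelic(h)
                n_a, n_b = len(h.alleles_a), len(h.alleles_b)
            else:
                aa, ab, pa, pb, d_comp = composite_delta(ga, gb)
                dp = _dprime_from_d(d_comp, pa, pb)
                r2 = _r2_from_d(d_comp, pa, pb)
                n_a, n_b = len(aa), len(ab)
            _, _, pa_c, pb_c, d_comp = composite_delta(ga, gb)
            cdp = _dprime_from_d(d_comp, pa_c, pb_c)
            cr2 = _r2_from_d(d_comp, pa_c, pb_c)
        except MonomorphicLocusError:
            continue
        records.append(
            {
                "unit": unit,
                "locusA": row.locusA,
                "locusB": row.locusB,
                "lg": row.lg,
                "distance_mb": row.distance_mb,
                "dprime": dp,
                "r2": r2,
                "composite_dprime": cdp,
                "composite_r2": cr2,
                "n_alleles_A": n_a,
                "n_alleles_B": n_b,
                "n_individuals": ga.shape[0],
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "unit", "locusA", "locusB", "lg", "distance_mb", "dprime", "r2",
            "composite_dprime", "composite_r2", "n_alleles_A", "n_alleles_B",
            "n_individuals",
        ],
    )


# ---------------------------------------------------------------------------
# Distance binning, decay regression, measure correlation
# ---------------------------------------------------------------------------

BIN_EDGES = (0.0, 5.0, 10.0, 15.0, 20.0)
BIN_LABELS = ("0-5 Mb", "5.001-10 Mb", "10.001-15 Mb", "15.001-20 Mb", ">20 Mb")


def bin_ld_by_distance(records: pd.DataFrame, value: str = "dprime") -> pd.DataFrame:
    """Mean D' with estimation error (SD / sqrt(n_pairs)) in right-closed
    distance bins plus an overall (all syntenic pairs) row; empty bins are
    omitted."""
    if records.empty:
        raise ValueError("no LD records to bin")
    d = records["distance_mb"].to_numpy(dtype=float)
    v = records[value].to_numpy(dtype=float)
    # right-closed: bin k holds edges[k] < d <= edges[k+1]; last is > 20 Mb
    idx = np.searchsorted(BIN_EDGES[1:], d, side="left")
    rows = []
    for k, label in enumerate(BIN_LABELS):
        vals = v[idx == k]
        if vals.size == 0:
            continue
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        rows.append(
            {
                "bin": label,
                "mean": float(vals.mean()),
                "error": float(sd / np.sqrt(vals.size)),
                "n_pairs": int(vals.size),
            }
        )
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    rows.append(
        {
            "bin": "overall",
            "mean": float(v.mean()),
            "error": float(sd / np.sqrt(v.size)),
            "n_pairs": int(v.size),
        }
    )
    return pd.DataFrame(rows)


@dataclass
class DecayFit:
    """OLS fit of D' on ln(distance in Mb)."""

    intercept: float
    slope: float
    r_squared: float
    p_value: float
    half_length_mb: float | None
    n_pairs: int
    degenerate: bool = False


def fit_ld_decay(records: pd.DataFrame, value: str = "dprime") -> DecayFit:
    """Logarithmic decay regression D' ~ ln(distance_mb).

    The LD half-length is the distance at which the fitted curve crosses 0.5,
    exp((0.5 - intercept)/slope); it is undefined unless the slope is
    negative.
    """
    rec = records[records["distance_mb"] > 0]
    if len(rec) < 3:
        raise ValueError("need >= 3 records with positive distance")
    x = np.log(rec["distance_mb"].to_numpy(dtype=float))
    y = rec[value].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return DecayFit(float(y.mean()), 0.0, 0.0, 1.0, None, len(rec), degenerate=True)
    if np.ptp(y) == 0:
        # constant response: slope 0, no explained variance
        return DecayFit(float(y[0]), 0.0, 0.0, 1.0, None, len(rec))
    fit = stats.linregress(x, y)
    half = None
    if fit.slope < 0:
        half = float(np.exp((0.5 - fit.intercept) / fit.slope))
    return DecayFit(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        half_length_mb=half,
        n_pairs=len(rec),
    )


def ld_measure_correlation(records: pd.DataFrame):
    """Pearson and Kendall correlations between paired D' and r^2 values.

    Returns ``(pearson_r, pearson_p, kendall_tau, kendall_p)``.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 records")
    x = records["dprime"].to_numpy(dtype=float)
    y = records["r2"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the LD measures")
    pr = stats.pearsonr(x, y)
    kt = stats.kendalltau(x, y)
    return (
        float(pr.statistic),
        float(pr.pvalue),
        float(kt.statistic),
        float(kt.pvalue),
    )
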