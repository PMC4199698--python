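"""Population differentiation and within-population relatedness.

Pairwise F_ST is the Weir & Cockerham (1984) theta, combined over loci as a
ratio of summed variance components, with significance from permutation of
individuals between the two populations.  A three-level AMOVA (among groups /
among populations within groups / within populations) decomposes molecular
variance on the allele-identity distance (0 if two gene copies carry the same
allele, 1 otherwise), with the standard permutation schemes per level.
Within-population relatedness uses Queller & Goodnight's estimator with
allele frequencies computed excluding the focal pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeDataset, ValidationError


class UndefinedStatistic(ValueError):
    pass


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components_locus(genos: list[np.ndarray]):
    """Summed W&C (1984) variance components (a, b, c) over alleles at one
    locus for r >= 2 samples.  ``genos``: per population an (n_i, 2) array of
    allele codes, missing rows already removed."""
    genos = [g for g in genos if g.shape[0] > 0]
    r = len(genos)
    if r < 2:
        return 0.0, 0.0, 0.0
    ns = np.array([g.shape[0] for g in genos], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in genos]))
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([(g == allele).mean() for g in genos])  # dose/2n
        h_i = np.array([((g == allele).sum(axis=1) == 1).mean() for g in genos])
        pbar = (ns * p_i).sum() / (r * nbar)
        s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _theta_from_genotype_arrays(pop_arrays: list[np.ndarray]) -> float:
    """Multilocus theta from per-population (n_i, L, 2) genotype arrays."""
    n_loci = pop_arrays[0].shape[1]
    a_tot = d_tot = 0.0
    for l in range(n_loci):
        genos = []
        for arr in pop_arrays:
            g = arr[:, l, :]
            g = g[(g != MISSING).all(axis=1)]
            genos.append(g)
        a, b, c = _wc_components_locus(genos)
        a_tot += a
        d_tot += a + b + c
    if d_tot == 0:
        raise UndefinedStatistic("no shared polymorphic locus")
    return a_tot / d_tot


def pairwise_fst(dataset: GenotypeDataset, popA: str, popB: str) -> float:
    """Weir-Cockerham theta between two populations (ratio of summed
    components over shared polymorphic loci)."""
    a = dataset.population(popA).genotypes
    b = dataset.population(popB).genotypes
    return _theta_from_genotype_arrays([a, b])


def fst_permutation_test(
    dataset: GenotypeDataset,
    popA: str,
    popB: str,
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation p-value for theta: individuals shuffled between the two
    populations; p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).

    Returns ``(theta_obs, p)``.
    """
    a = dataset.population(popA).genotypes
    b = dataset.population(popB).genotypes
    theta_obs = _theta_from_genotype_arrays([a, b])
    pooled = np.concatenate([a, b], axis=0)
    na = a.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        try:
            t = _theta_from_genotype_arrays([pooled[perm[:na]], pooled[perm[na:]]])
        except UndefinedStatistic:
            t = 0.0
        if t >= theta_obs:
            count += 1
    return theta_obs, (1 + count) / (n_perm + 1)


def fst_matrix(
    dataset: GenotypeDataset,
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise theta (and p-values when n_perm > 0) for all populations."""
    names = dataset.population_names
    rows = []
    rng = np.random.default_rng(seed)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if n_perm:
                theta, p = fst_permutation_test(
                    dataset, names[i], names[j], n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                )
            else:
                theta, p = pairwise_fst(dataset, names[i], names[j]), np.nan
            rows.append({"popA": names[i], "popB": names[j], "theta": theta, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    grouping: str
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    percent_a: float
    percent_b: float
    percent_c: float
    p_a: float | None = None
    p_b: float | None = None
    p_c: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grouping": self.grouping,
                "component": [
                    "among_groups",
                    "among_populations_within_groups",
                    "within_populations",
                ],
                "variance": [self.sigma_a, self.sigma_b, self.sigma_c],
                "percent": [self.percent_a, self.percent_b, self.percent_c],
                "p": [self.p_a, self.p_b, self.p_c],
            }
        )


def _amova_components(pop_arrays, group_of: np.ndarray):
    """Summed three-level variance components over loci.

    ``pop_arrays``: per population (n_i, L, 2) genotype arrays;
    ``group_of``: group index per population.  Distance between gene copies is
    0/1 allele identity, so within-unit sums of squared deviations reduce to
    (n^2 - sum_a c_a^2) / (2n) computed from allele counts.
    """
    n_loci = pop_arrays[0].shape[1]
    n_groups = int(group_of.max()) + 1
    sa = sb = sc = 0.0
    for l in range(n_loci):
        cols = []
        for arr in pop_arrays:
            copies = arr[:, l, :].ravel()
            cols.append(copies[copies != MISSING])
        sizes = np.array([c.size for c in cols], dtype=float)
        if sizes.sum() == 0:
            continue
        alleles = np.unique(np.concatenate(cols))
        counts = np.array(
            [[np.sum(c == a) for a in alleles] for c in cols], dtype=float
        )  # (pops, alleles)

        def ssd(count_rows):
            n = count_rows.sum()
            if n == 0:
                return 0.0
            return (n**2 - (count_rows**2).sum()) / (2.0 * n)

        N = sizes.sum()
        ssd_total = ssd(counts.sum(axis=0))
        ssd_wp = sum(ssd(counts[i]) for i in range(len(cols)))
        group_counts = np.zeros((n_groups, len(alleles)))
        for i, g in enumerate(group_of):
            group_counts[g] += counts[i]
        ssd_wg = sum(ssd(group_counts[g]) for g in range(n_groups))
        ssd_ap = ssd_wg - ssd_wp
        ssd_ag = ssd_total - ssd_wg

        P = int((sizes > 0).sum())
        present_groups = {
            int(group_of[i]) for i in range(len(cols)) if sizes[i] > 0
        }
        G = len(present_groups)
        df_c = N - P
        df_b = P - G
        df_a = G - 1

        sigma_c = ssd_wp / df_c if df_c > 0 else 0.0
        group_sizes = np.array(
            [sizes[group_of == g].sum() for g in range(n_groups)]
        )
        # unequal-size coefficients (Excoffier's n', n'' and n''')
        with np.errstate(invalid="ignore", divide="ignore"):
            sum_sq_over_group = np.nansum(
                np.array(
                    [
                        (sizes[group_of == g] ** 2).sum() / group_sizes[g]
                        if group_sizes[g] > 0
                        else 0.0
                        for g in range(n_groups)
                    ]
                )
            )
        n1 = (N - sum_sq_over_group) / df_b if df_b > 0 else 0.0
        sigma_b = (
            (ssd_ap / df_b - sigma_c) / n1 if df_b > 0 and n1 > 0 else 0.0
        )
        if df_a > 0:
            n2 = (sum_sq_over_group - (sizes**2).sum() / N) / df_a
            n3 = (N - (group_sizes**2).sum() / N) / df_a
            ms_ag = ssd_ag / df_a
            sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
        else:
            sigma_a = 0.0
        sa += sigma_a
        sb += sigma_b
        sc += sigma_c
    return sa, sb, sc


def amova(
    dataset: GenotypeDataset,
    grouping: dict[str, str],
    n_perm: int = 0,
    seed: int | None = None,
    name: str = "grouping",
) -> AmovaResult:
    """Three-level AMOVA on allele-identity distance.

    ``grouping`` maps population name -> group label.  Significance (when
    ``n_perm > 0``) uses the standard schemes: whole populations permuted
    among groups for the among-group component; individuals permuted among
    populations within groups for the among-population component; individuals
    permuted among all populations for the within-population level (tested
    through the total differentiation sigma_a + sigma_b).
    """
    names = dataset.population_names
    unknown = set(grouping) - set(names)
    if unknown:
        raise ValidationError(f"grouping references unknown populations {unknown}")
    missing = set(names) - set(grouping)
    if missing:
        raise ValidationError(f"grouping omits populations {missing}")
    labels = sorted({grouping[n] for n in names})
    group_of = np.array([labels.index(grouping[n]) for n in names])
    pop_arrays = [p.genotypes for p in dataset.populations]

    sa, sb, sc = _amova_components(pop_arrays, group_of)
    total = sa + sb + sc
    result = AmovaResult(
        grouping=name,
        sigma_a=sa,
        sigma_b=sb,
        sigma_c=sc,
        percent_a=100 * sa / total,
        percent_b=100 * sb / total,
        percent_c=100 * sc / total,
    )
    if n_perm <= 0:
        return result

    rng = np.random.default_rng(seed)
    sizes = [arr.shape[0] for arr in pop_arrays]
    pooled = np.concatenate(pop_arrays, axis=0)
    bounds = np.cumsum([0] + sizes)

    count_a = count_b = count_c = 0
    for _ in range(n_perm):
        # among groups: permute population labels across groups
        ga = group_of[rng.permutation(len(group_of))]
        pa, _, _ = _amova_components(pop_arrays, ga)
        if pa >= sa:
            count_a += 1
        # among populations within groups: shuffle individuals within groups
        perm = np.arange(pooled.shape[0])
        for g in range(group_of.max() + 1):
            pops_in_g = np.where(group_of == g)[0]
            idx = np.concatenate(
                [np.arange(bounds[p], bounds[p + 1]) for p in pops_in_g]
            )
            perm[idx] = rng.permutation(idx)
        arrays_b = [pooled[perm[bounds[i]:bounds[i + 1]]] for i in range(len(sizes))]
        _, pb, _ = _amova_components(arrays_b, group_of)
        if pb >= sb:
            count_b += 1
        # overall: shuffle individuals among all populations
        perm = rng.permutation(pooled.shape[0])
        arrays_c = [pooled[perm[bounds[i]:bounds[i + 1]]] for i in range(len(sizes))]
        ca, cb, _ = _amova_components(arrays_c, group_of)
        if ca + cb >= sa + sb:
            count_c += 1
    result.p_a = (1 + count_a) / (n_perm + 1)
    result.p_b = (1 + count_b) / (n_perm + 1)
    result.p_c = (1 + count_c) / (n_perm + 1)
    return result


# ---------------------------------------------------------------------------
# Queller & Goodnight relatedness
# ---------------------------------------------------------------------------

def relatedness_qg(dataset: GenotypeDataset, population: str) -> pd.DataFrame:
    """Pairwise Queller-Goodnight relatedness within one population.

    Reference allele frequencies for each pair exclude the two focal
    individuals (bias correction); the estimate is the ratio of sums over
    loci, averaged over the two reference orderings.  Returns a symmetric
    DataFrame indexed by individual.
    """
    pop = dataset.population(population)
    n = pop.n_individuals
    if n < 2:
        raise UndefinedStatistic("need >= 2 individuals")
    g = pop.genotypes
    r = np.full((n, n), np.nan)

    def _qg_directional(gx, gy, freqs_list):
        num = den = 0.0
        informative = False
        for l, freqs in enumerate(freqs_list):
            if freqs is None:
                continue
            a, b = gx[l]
            c, d = gy[l]
            if a == MISSING or c == MISSING:
                continue
            pa = freqs.get(int(a), 0.0)
            pb = freqs.get(int(b), 0.0)
            num += 0.5 * (
                float(a == c) + float(a == d) + float(b == c) + float(b == d)
            ) - pa - pb
            den += 1.0 + float(a == b) - pa - pb
            informative = True
        if not informative or den == 0:
            return np.nan
        return num / den

    for i in range(n):
        for j in range(i + 1, n):
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            freqs_list = []
            for l in range(dataset.n_loci):
                copies = g[mask, l, :].ravel()
                copies = copies[copies != MISSING]
                if copies.size == 0 or len(np.unique(copies)) < 2:
                    freqs_list.append(None)
                    continue
                alleles, counts = np.unique(copies, return_counts=True)
                freqs_list.append(
                    dict(zip(alleles.astype(int).tolist(), (counts / copies.size)))
                )
            rij = _qg_directional(g[i], g[j], freqs_list)
            rji = _qg_directional(g[j], g[i], freqs_list)
            vals = [v for v in (rij, rji) if np.isfinite(v)]
            if not vals:
                raise UndefinedStatistic(
                    f"relatedness undefined for pair ({i}, {j}): no polymorphic data"
                )
            r[i, j] = r[j, i] = float(np.mean(vals))
    names = pop.individual_names or [f"ind{k}" for k in range(n)]
    return pd.DataFrame(r, index=names, columns=names)
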