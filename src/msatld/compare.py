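"""Habitat- and population-level statistical comparisons of LD values.

Mann-Whitney U (normal approximation with tie correction) between two sets of
D' records, Kruskal-Wallis across several, a nested ANCOVA of D' on habitat
and population-within-habitat with marker distance as covariate, and
Bonferroni adjustment.  The habitat effect is tested against the
population-within-habitat mean square (the classical expected-mean-squares
treatment of a nested design), populations against the residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def mann_whitney(values_a, values_b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation.

    Returns ``(U, Z, p)`` where U is the statistic of the first sample.  If
    every value is tied across both samples, Z = 0 and p = 1.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1.0)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u == 0:
        return float(u1), 0.0, 1.0
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u1), float(z), float(min(p, 1.0))


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square reference.

    Returns ``(H, df, p)``; df = number of groups - 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


@dataclass
class AncovaRow:
    term: str
    ss: float
    df: int
    ms: float
    f: float | None
    df_error: int | None
    p: float | None


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _dummies(labels: np.ndarray) -> np.ndarray:
    cats = pd.unique(labels)
    return (labels[:, None] == cats[None, :]).astype(float)[:, 1:]


def ancova_ld(
    records: pd.DataFrame,
    value: str = "dprime",
    log_distance: bool = False,
) -> pd.DataFrame:
    """Nested ANCOVA: D' ~ distance + habitat + population(habitat).

    ``records`` needs columns ``population``, ``habitat``, ``distance_mb``
    and the response.  Sequential (type I) sums of squares with the covariate
    entered first; the habitat F uses the population-within-habitat mean
    square as error (nested design), populations use the residual.  With one
    population per habitat the habitat test is confounded and flagged
    untestable (F and p are NaN).
    """
    y = records[value].to_numpy(dtype=float)
    d = records["distance_mb"].to_numpy(dtype=float)
    if log_distance:
        if (d <= 0).any():
            raise ValueError("log distance requires positive distances")
        d = np.log(d)
    hab = records["habitat"].to_numpy()
    pop = records["population"].to_numpy()
    n = y.size
    n_hab = len(pd.unique(hab))
    n_pop = len(pd.unique(pop))
    if n_hab < 2:
        raise ValueError("need >= 2 habitats")

    one = np.ones((n, 1))
    Xd = np.column_stack([one, d])
    Xh = np.column_stack([Xd, _dummies(hab)])
    # population nested in habitat: full population dummies span habitat too
    Xp = np.column_stack([Xd, _dummies(pop)])

    ss_total = float(((y - y.mean()) ** 2).sum())
    rss_0 = float(((y - y.mean()) ** 2).sum())
    rss_d = _ols_rss(y, Xd)
    rss_h = _ols_rss(y, Xh)
    rss_p = _ols_rss(y, Xp)

    ss_dist = rss_0 - rss_d
    ss_hab = rss_d - rss_h
    ss_pop = rss_h - rss_p
    ss_res = rss_p

    df_dist = 1
    df_hab = n_hab - 1
    df_pop = n_pop - n_hab
    df_res = n - n_pop - 1  # intercept + covariate + population dummies

    ms_hab = ss_hab / df_hab if df_hab else np.nan
    ms_pop = ss_pop / df_pop if df_pop > 0 else np.nan
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    rows = []
    f_d = (ss_dist / df_dist) / ms_res if df_res > 0 else None
    rows.append(
        AncovaRow(
            "distance", ss_dist, df_dist, ss_dist / df_dist,
            f_d, df_res, float(stats.f.sf(f_d, df_dist, df_res)) if f_d is not None else None,
        )
    )
    if df_pop > 0:
        f_h = ms_hab / ms_pop
        rows.append(
            AncovaRow(
                "habitat", ss_hab, df_hab, ms_hab,
                float(f_h), df_pop, float(stats.f.sf(f_h, df_hab, df_pop)),
            )
        )
        f_p = ms_pop / ms_res
        rows.append(
            AncovaRow(
                "population(habitat)", ss_pop, df_pop, ms_pop,
                float(f_p), df_res, float(stats.f.sf(f_p, df_pop, df_res)),
            )
        )
    else:
        # one population per habitat: habitat effect confounded with population
        rows.append(AncovaRow("habitat", ss_hab, df_hab, ms_hab, None, None, None))
        rows.append(AncovaRow("population(habitat)", ss_pop, 0, np.nan, None, None, None))
    rows.append(AncovaRow("residual", ss_res, df_res, ms_res, None, None, None))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.attrs["ss_total"] = ss_total
    return out


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-adjusted p-values: min(1, p * m) for a family of m tests."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, p * m)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """The alpha/m significance threshold form (e.g. 0.05/78 = 0.000641)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def comparison_report(tests: list[dict]) -> pd.DataFrame:
    """Assemble a family of test results and attach Bonferroni-adjusted p.

    Each entry needs keys ``test``, ``grouping``, ``statistic``, ``df``,
    ``p``; the family size is the number of entries.
    """
    df = pd.DataFrame(tests)
    m = len(df)
    df["m"] = m
    df["p_bonferroni"] = bonferroni(df["p"].to_numpy(), m)
    return df
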