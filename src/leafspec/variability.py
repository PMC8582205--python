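"""Inter- and intraspecific trait variability statistics.

Intraspecific variability is summarised by the coefficient of variation of
each trait within each species at peak of growth (a configurable month
filter, July by default).  Differences between species are tested with the
non-parametric Kruskal-Wallis omnibus test followed by Dunn's pairwise
post-hoc z tests with Benjamini-Hochberg false-discovery-rate adjustment;
trait redundancy is screened with a pairwise Pearson correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupedTraits",
    "coefficient_of_variation",
    "kruskal_wallis",
    "dunn_posthoc_bh",
    "trait_correlation_matrix",
    "cv_table",
    "peak_growth_subset",
]


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) over the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


@dataclass
class GroupedTraits:
    """One trait's values grouped by species."""

    groups: dict
    trait: str = ""
    subset_rule: str = ""

    def __post_init__(self) -> None:
        self.groups = {
            k: np.asarray(v, dtype=float) for k, v in self.groups.items()
        }

    def nonempty(self) -> dict:
        return {k: v for k, v in self.groups.items() if v.size > 0}

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        trait: str,
        species_col: str = "species",
        subset_rule: str = "",
    ) -> "GroupedTraits":
        groups = {
            sp: sub[trait].dropna().to_numpy(dtype=float)
            for sp, sub in table.groupby(species_col)
        }
        return cls(groups=groups, trait=trait, subset_rule=subset_rule)


def peak_growth_subset(
    table: pd.DataFrame, date_col: str = "date", months: tuple[int, ...] = (7,)
) -> pd.DataFrame:
    """Rows sampled at peak of growth (default: July) by the date column."""
    month = pd.to_datetime(table[date_col]).dt.month
    return table[month.isin(months)]


def kruskal_wallis(grouped: GroupedTraits) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    samples = list(grouped.nonempty().values())
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 non-empty groups")
    if sum(s.size for s in samples) < 3:
        raise ValueError("too few observations")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        raise ValueError("undefined for identical values in all groups")
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def dunn_posthoc_bh(grouped: GroupedTraits) -> pd.DataFrame:
    """Dunn's pairwise rank z tests with BH adjustment.

    Uses pooled average ranks with the standard tie correction in the
    variance term; returns one row per unordered group pair with z, the
    two-sided raw p and the Benjamini-Hochberg adjusted p.
    """
    groups = grouped.nonempty()
    if len(groups) < 2:
        raise ValueError("Dunn's test needs at least 2 non-empty groups")
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for g in labels:
        size = groups[g].size
        mean_rank[g] = ranks[start : start + size].mean()
        start += size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    rows = []
    for g1, g2 in combinations(labels, 2):
        n1, n2 = groups[g1].size, groups[g2].size
        se = np.sqrt(base_var * (1.0 / n1 + 1.0 / n2))
        z = 0.0 if se == 0 else (mean_rank[g1] - mean_rank[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(dict(group1=g1, group2=g2, z=float(z), p_raw=float(p)))
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, mark in _STAR_LEVELS:
        if p < level:
            return mark
    return ""


def trait_correlation_matrix(
    table: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between traits.

    Returns (r, p, stars) DataFrames; constant or too-short pairs are NaN
    with empty stars.  Significance stars at 0.05 / 0.01 / 0.001.
    """
    if traits is None:
        traits = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    stars = pd.DataFrame("", index=traits, columns=traits)
    for t1, t2 in combinations(traits, 2):
        sub = table[[t1, t2]].dropna()
        if len(sub) < 3 or sub[t1].nunique() < 2 or sub[t2].nunique() < 2:
            rv, pv = np.nan, np.nan
        else:
            rv, pv = stats.pearsonr(sub[t1], sub[t2])
        r.loc[t1, t2] = r.loc[t2, t1] = rv
        p.loc[t1, t2] = p.loc[t2, t1] = pv
        mark = "" if not np.isfinite(pv) else _stars(pv)
        stars.loc[t1, t2] = stars.loc[t2, t1] = mark
    return r, p, stars


def cv_table(
    table: pd.DataFrame,
    traits: list[str],
    species_col: str = "species",
    date_col: str = "date",
    months: tuple[int, ...] = (7,),
) -> pd.DataFrame:
    """Per-species CV of each trait at peak of growth (species x trait)."""
    sub = peak_growth_subset(table, date_col=date_col, months=months)
    rows = {}
    for sp, grp in sub.groupby(species_col):
        rows[sp] = {
            t: coefficient_of_variation(grp[t].dropna())
            if grp[t].dropna().size >= 2
            else np.nan
            for t in traits
        }
    return pd.DataFrame(rows).T[traits]
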