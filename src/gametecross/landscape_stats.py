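"""Recombination landscapes and group statistics.

Landscapes are per-(chromosome, 10%-window) crossover frequencies (events per
gamete) converted to cM/Mb: each crossover observed in a sampled chromatid
contributes ``100 / n_gametes`` cM to its window, so a window's rate is
``frequency * 100 / window_Mb`` and the genome-wide rate is mean crossovers
per nucleus times 100 over the genome size in Mb.

Group comparisons follow standard quantitative-genetics practice: one-way
ANOVA with Tukey's HSD over the subpopulation x treatment cells for trait
means; Pearson correlation plus per-window chi-square tests (recombinant vs
non-recombinant gametes per condition) with Benjamini-Hochberg FDR control
for landscape shape; Spearman rank correlation for additive allele stacking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .crossover import CrossoverConfig
from .genotype_io import MarkerMap

__all__ = [
    "Landscape",
    "LandscapeComparison",
    "GroupEffects",
    "StackingResult",
    "build_landscape",
    "compare_landscapes",
    "group_effects",
    "allele_stacking",
    "plot_landscape",
]


@dataclass
class Landscape:
    """Per-window crossover frequencies for one group of gametes."""

    table: pd.DataFrame  # chromosome, window, n_events, n_recombinant, frequency, window_mb, rate_cm_per_mb
    n_gametes: int
    genome_mb: float
    label: str = ""

    @property
    def genome_wide_rate(self) -> float:
        """Mean cM/Mb over the genome (mean COs per gamete * 100 / genome Mb)."""
        return float(self.table["n_events"].sum() / self.n_gametes * 100.0 / self.genome_mb)


def build_landscape(
    events: pd.DataFrame,
    n_gametes: int,
    marker_map: MarkerMap,
    cfg: CrossoverConfig | None = None,
    label: str = "",
) -> Landscape:
    """Aggregate called events into a per-(chromosome, window) landscape."""
    if n_gametes <= 0:
        raise ValueError("n_gametes must be positive")
    cfg = cfg or CrossoverConfig()
    n_win = cfg.n_windows
    rows = []
    for chrom in marker_map.chromosomes:
        chrom_mb = marker_map.chrom_lengths_bp[chrom] / 1e6
        sub = events[events["chromosome"] == chrom] if len(events) else events
        if len(sub):
            widx = np.minimum(
                (sub["position_rel"].to_numpy() / cfg.window_fraction).astype(int), n_win - 1
            )
            counts = np.bincount(widx, minlength=n_win)
            recomb = [
                sub.loc[widx == w, "nucleus_id"].nunique() for w in range(n_win)
            ]
        else:
            counts = np.zeros(n_win, dtype=int)
            recomb = np.zeros(n_win, dtype=int)
        for w in range(n_win):
            freq = counts[w] / n_gametes
            win_mb = chrom_mb * cfg.window_fraction
            rows.append(
                {
                    "chromosome": chrom,
                    "window": w,
                    "n_events": int(counts[w]),
                    "n_recombinant": int(recomb[w]),
                    "frequency": freq,
                    "window_mb": win_mb,
                    "rate_cm_per_mb": freq * 100.0 / win_mb,
                }
            )
    return Landscape(
        table=pd.DataFrame(rows),
        n_gametes=int(n_gametes),
        genome_mb=marker_map.genome_length_bp / 1e6,
        label=label,
    )


@dataclass
class LandscapeComparison:
    pearson_r: float
    pearson_p: float
    per_window: pd.DataFrame  # chromosome, window, chi2, p_raw, p_fdr

    @property
    def n_significant(self) -> int:
        return int((self.per_window["p_fdr"] < 0.05).sum())


def compare_landscapes(
    a: Landscape, b: Landscape, correction: bool = True
) -> LandscapeComparison:
    """Correlate two landscapes and test per-window frequency differences.

    The per-window test is a 2x2 chi-square on recombinant vs non-recombinant
    gamete counts in the two groups, BH-FDR adjusted across all windows.
    ``correction`` applies the Yates continuity correction (the default of
    R's ``chisq.test``, mildly conservative); windows with no recombinants in
    either group get p = 1.
    """
    key = ["chromosome", "window"]
    if not a.table[key].reset_index(drop=True).equals(b.table[key].reset_index(drop=True)):
        raise ValueError("landscapes are on different window grids")
    fa, fb = a.table["frequency"].to_numpy(), b.table["frequency"].to_numpy()
    r, p = sps.pearsonr(fa, fb)
    raw = np.ones(len(fa))
    chi = np.zeros(len(fa))
    ra = a.table["n_recombinant"].to_numpy()
    rb = b.table["n_recombinant"].to_numpy()
    for i in range(len(fa)):
        tab = np.array([[ra[i], a.n_gametes - ra[i]], [rb[i], b.n_gametes - rb[i]]])
        if tab[:, 0].sum() == 0 or (tab.sum(axis=1) == 0).any():
            continue
        chi2, pval, _, _ = sps.chi2_contingency(tab, correction=correction)
        chi[i], raw[i] = chi2, pval
    _, p_fdr, _, _ = multipletests(raw, method="fdr_bh")
    per_window = a.table[key].copy()
    per_window["chi2"] = chi
    per_window["p_raw"] = raw
    per_window["p_fdr"] = p_fdr
    return LandscapeComparison(pearson_r=float(r), pearson_p=float(p), per_window=per_window)


@dataclass
class GroupEffects:
    trait: str
    anova: pd.DataFrame
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    group_means: pd.Series

    def contrast(self, group1: str, group2: str) -> pd.Series:
        t = self.tukey
        hit = t[((t.group1 == group1) & (t.group2 == group2)) | ((t.group1 == group2) & (t.group2 == group1))]
        if hit.empty:
            raise KeyError(f"no contrast {group1} vs {group2}")
        return hit.iloc[0]


def group_effects(
    traits: pd.DataFrame,
    trait: str = "cc_per_chromatid",
    by: tuple[str, ...] = ("subpopulation", "treatment"),
) -> GroupEffects:
    """One-way ANOVA and Tukey HSD over group cells for one trait.

    Cells are the crossed levels of ``by`` (default subpopulation x
    treatment). Records with a null trait value are dropped; a cell with fewer
    than two records is skipped with a warning.
    """
    data = traits.dropna(subset=[trait, *by]).copy()
    data["_group"] = data[list(by)].astype(str).agg(":".join, axis=1)
    sizes = data.groupby("_group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        import warnings

        warnings.warn(f"group(s) {small} have < 2 records; skipped")
        data = data[~data["_group"].isin(small)]
    if data["_group"].nunique() < 2:
        raise ValueError("need at least two groups with >= 2 records")
    model = ols(f"Q('{trait}') ~ C(_group)", data=data).fit()
    anova = anova_lm(model, typ=2)
    hsd = pairwise_tukeyhsd(data[trait].to_numpy(), data["_group"].to_numpy())
    from itertools import combinations

    pairs = list(combinations(hsd.groupsunique, 2))
    tukey = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "meandiff": hsd.meandiffs,
            "p_adj": hsd.pvalues,
            "lower": hsd.confint[:, 0],
            "upper": hsd.confint[:, 1],
            "reject": hsd.reject,
        }
    )
    return GroupEffects(
        trait=trait,
        anova=anova,
        tukey=tukey,
        group_means=data.groupby("_group")[trait].mean(),
    )


@dataclass
class StackingResult:
    stacked: pd.DataFrame  # m, n_individuals, mean_trait (null when subset empty)
    spearman_rho: float
    spearman_p: float


def allele_stacking(
    traits: pd.DataFrame,
    indicators: pd.DataFrame,
    trait: str = "cc_per_chromatid",
) -> StackingResult:
    """Additivity of beneficial alleles by stacking.

    ``indicators`` is an individuals x alleles 0/1 matrix whose columns are
    ordered by decreasing allele frequency. For each m, the subset of
    individuals carrying all of the first m alleles is averaged; the Spearman
    correlation is computed between each individual's total number of
    beneficial alleles and its trait value.
    """
    by_ind = traits.set_index("individual_id")[trait]
    common = by_ind[by_ind.index.isin(indicators.index)]
    ind = indicators.loc[common.index].to_numpy()
    rows = []
    for m in range(1, ind.shape[1] + 1):
        carriers = (ind[:, :m] == 1).all(axis=1)
        rows.append(
            {
                "m": m,
                "n_individuals": int(carriers.sum()),
                "mean_trait": float(common[carriers].mean()) if carriers.any() else np.nan,
            }
        )
    n_carried = ind.sum(axis=1)
    rho, pval = sps.spearmanr(n_carried, common.to_numpy())
    return StackingResult(stacked=pd.DataFrame(rows), spearman_rho=float(rho), spearman_p=float(pval))


def plot_landscape(landscapes, marker_map: MarkerMap, ax=None):  # pragma: no cover - plotting
    """Line plot of cM/Mb per window for one or more landscapes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    if isinstance(landscapes, Landscape):
        landscapes = [landscapes]
    chroms = marker_map.chromosomes
    n_win = landscapes[0].table["window"].max() + 1
    for ls in landscapes:
        y, x = [], []
        for ci, chrom in enumerate(chroms):
            sub = ls.table[ls.table["chromosome"] == chrom].sort_values("window")
            x.extend(ci * (n_win + 1) + sub["window"])
            y.extend(sub["rate_cm_per_mb"])
        ax.plot(x, y, marker="o", ms=2, label=ls.label or None)
    ax.set_xticks([i * (n_win + 1) + n_win / 2 for i in range(len(chroms))])
    ax.set_xticklabels(chroms)
    ax.set_ylabel("cM/Mb")
    if any(ls.label for ls in landscapes):
        ax.legend()
    return ax
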