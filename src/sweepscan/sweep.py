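"""Dual-outlier selective-sweep scanning.

For each reference-vs-test comparison the windowed pi-ratio
(pi_reference / pi_test; large values mean diversity loss in the test
population) and F_ST are thresholded at their empirical top-5%
(nearest-rank quantile, inclusive >=). A window is a sweep candidate iff
it exceeds both thresholds simultaneously; candidate windows overlapping
or abutting on a chromosome merge into loci, genes are assigned by >=1 bp
overlap with the locus, and loci shared across all comparisons are the
intersection of the per-comparison outlier-window sets.

Windows where the test population has zero diversity have an undefined
(infinite) ratio: they are excluded from quantile computation but do
qualify as outliers when their F_ST passes — zero test diversity against
nonzero reference diversity is the extreme form of the scanned signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SweepLocus

DEFAULT_QUANTILE = 0.95


@dataclass
class ComparisonResult:
    comparison: str
    stats: pd.DataFrame  # per-window stats incl. pi_ratio and outlier flag
    t_fst: float
    t_ratio: float
    loci: list = field(default_factory=list)

    @property
    def outlier_windows(self) -> pd.DataFrame:
        return self.stats[self.stats["outlier"]]

    @property
    def genes(self) -> list:
        seen = []
        for locus in self.loci:
            for g in locus.genes:
                if g not in seen:
                    seen.append(g)
        return seen


def pi_ratio(pi_ref, pi_test):
    """Windowed pi-ratio, reference over test; +inf where pi_test = 0 and
    pi_ref > 0, NaN where both are 0."""
    pi_ref = np.asarray(pi_ref, float)
    pi_test = np.asarray(pi_test, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return pi_ref / pi_test


def empirical_threshold(values, q: float = DEFAULT_QUANTILE) -> float:
    """Nearest-rank upper quantile: the value at rank ceil(q*n) of the
    ascending sort of the finite values; selection downstream is
    inclusive (>=). Requires at least 20 finite values."""
    v = np.asarray(values, float)
    v = np.sort(v[np.isfinite(v)])
    if len(v) < 20:
        raise ValueError(
            f"only {len(v)} finite values; need >= 20 for a stable empirical "
            "threshold — enlarge the genome or simulation")
    rank = int(np.ceil(q * len(v)))  # 1-based
    return float(v[rank - 1])


def select_outlier_windows(stats: pd.DataFrame, t_fst: float, t_ratio: float) -> pd.Series:
    """Joint dual-threshold outlier flag: a window is an outlier iff
    fst >= t_fst AND pi_ratio >= t_ratio in that same window (infinite
    ratios qualify), restricted to eligible windows."""
    ratio_ok = (stats["pi_ratio"] >= t_ratio) | np.isposinf(stats["pi_ratio"])
    return stats["eligible"] & (stats["fst"] >= t_fst) & ratio_ok


def merge_windows_to_loci(windows: pd.DataFrame) -> list:
    """Merge outlier windows that overlap or abut on one chromosome into
    SweepLocus records; locus statistics are maxima over member windows."""
    loci = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.start <= cur.end:
                cur.end = max(cur.end, row.end)
                cur.n_windows += 1
                cur.max_fst = max(cur.max_fst, row.fst)
                cur.max_pi_ratio = max(cur.max_pi_ratio, row.pi_ratio)
            else:
                if cur is not None:
                    loci.append(cur)
                cur = SweepLocus(chrom=chrom, start=int(row.start),
                                 end=int(row.end), n_windows=1,
                                 max_fst=float(row.fst),
                                 max_pi_ratio=float(row.pi_ratio))
        if cur is not None:
            loci.append(cur)
    return loci


def assign_genes(loci, gene_models, flank: int = 0):
    """Attach gene IDs to each locus by >= 1 bp overlap of the gene body
    (optionally extended by ``flank`` bp) with the locus interval."""
    from intervaltree import IntervalTree

    trees = {}
    for g in gene_models:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(g.start - flank, 0), g.end + flank, g.gene_id)
    for locus in loci:
        hits = trees.get(locus.chrom, IntervalTree()).overlap(locus.start, locus.end)
        locus.genes = sorted({iv.data for iv in hits})
    return loci


def scan_comparison(stats: pd.DataFrame, q: float = DEFAULT_QUANTILE,
                    gene_models=None, comparison: str = None) -> ComparisonResult:
    """Full scan for one comparison: ratio, thresholds, outliers, loci."""
    stats = stats.copy()
    stats["pi_ratio"] = pi_ratio(stats["pi_ref"], stats["pi_test"])
    eligible = stats[stats["eligible"]]
    finite_ratio = eligible["pi_ratio"][np.isfinite(eligible["pi_ratio"])]
    t_fst = empirical_threshold(eligible["fst"], q)
    t_ratio = empirical_threshold(finite_ratio, q)
    stats["outlier"] = select_outlier_windows(stats, t_fst, t_ratio)
    loci = merge_windows_to_loci(stats[stats["outlier"]])
    if gene_models is not None:
        assign_genes(loci, gene_models)
    label = comparison or (stats["comparison"].iloc[0] if "comparison" in stats
                           and len(stats) else "comparison")
    return ComparisonResult(comparison=label, stats=stats, t_fst=t_fst,
                            t_ratio=t_ratio, loci=loci)


def shared_loci(results, gene_models=None):
    """Windows, merged loci and genes shared by ALL comparisons.

    All comparisons must have been computed on the identical window grid.
    Returns ``(shared_windows, loci, genes)``.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 comparison results")
    grids = [list(zip(r.stats["chrom"], r.stats["start"], r.stats["end"]))
             for r in results]
    if any(g != grids[0] for g in grids[1:]):
        raise ValueError("comparisons were computed on different window grids")
    mask = np.logical_and.reduce([r.stats["outlier"].to_numpy() for r in results])
    base = results[0].stats
    shared = base.loc[mask, ["chrom", "start", "end"]].copy()
    # carry conservative per-window stats (minima across comparisons)
    shared["fst"] = np.minimum.reduce([r.stats.loc[mask, "fst"].to_numpy()
                                       for r in results])
    shared["pi_ratio"] = np.minimum.reduce([r.stats.loc[mask, "pi_ratio"].to_numpy()
                                            for r in results])
    loci = merge_windows_to_loci(shared)
    if gene_models is not None:
        assign_genes(loci, gene_models)
    genes = sorted({g for locus in loci for g in locus.genes})
    return shared, loci, genes


def venn_counts(results) -> pd.DataFrame:
    """Counts of outlier windows exclusive to each comparison, each pair,
    and common to all (Venn-diagram style regions)."""
    keys = [set(map(tuple, r.stats.loc[r.stats["outlier"],
                                       ["chrom", "start", "end"]].to_numpy()))
            for r in results]
    names = [r.comparison for r in results]
    rows = []
    n = len(keys)
    from itertools import combinations
    for size in range(1, n + 1):
        for combo in combinations(range(n), size):
            inset = set.intersection(*(keys[i] for i in combo))
            outset = set.union(set(), *(keys[i] for i in range(n) if i not in combo))
            rows.append(("&".join(names[i] for i in combo), len(inset - outset)))
    return pd.DataFrame(rows, columns=["region", "n_windows"])
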