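"""Windowed nucleotide diversity and F_ST.

Per-site quantities are computed from allele frequencies at biallelic
SNPs: unbiased diversity pi_site = (n/(n-1)) * 2p(1-p) with n the number
of called allele copies, and Weir & Cockerham (1984) two-population
variance components (a: among populations, b: among individuals within
populations, c: within individuals) from sample sizes, allele frequencies
and observed heterozygote proportions. Windows are 100 kb sliding in
10-kb steps by default; window pi sums site diversities over the window
and divides by the window span in bp, and window F_ST is the
ratio-of-sums sum(a) / sum(a+b+c), clamped at 0. A Hudson-style estimator
is available as an alternative for sensitivity checks.

Sites are usable for a comparison only where both populations have at
least two called allele copies (F_ST additionally needs more than one
called diploid in total). Windows with fewer than ``min_sites`` usable
sites are flagged ineligible and excluded from outlier thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, Window

WINDOW_SIZE = 100_000
WINDOW_STEP = 10_000


@dataclass
class WindowConfig:
    size: int = WINDOW_SIZE
    step: int = WINDOW_STEP
    min_sites: int = 10
    fst_estimator: str = "wc84"  # or "hudson"
    pi_denominator: str = "span"  # or "n_sites"

    def __post_init__(self) -> None:
        if not (self.size >= self.step > 0):
            raise ValueError("require size >= step > 0")
        if self.fst_estimator not in ("wc84", "hudson"):
            raise ValueError(f"unknown fst_estimator {self.fst_estimator!r}")
        if self.pi_denominator not in ("span", "n_sites"):
            raise ValueError(f"unknown pi_denominator {self.pi_denominator!r}")


def make_windows(chrom_lengths, size=WINDOW_SIZE, step=WINDOW_STEP):
    """Tile each chromosome with sliding windows.

    Starts run 0, step, 2*step, ... while start < L; end = min(start+size,
    L). Trailing windows shorter than ``size`` are kept but marked
    truncated.
    """
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    windows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, step):
            end = min(start + size, length)
            windows.append(Window(chrom, start, end, truncated=(end - start < size)))
    return windows


def site_freq(dosage_rows: np.ndarray):
    """Alt-allele frequency and called allele count per site for one
    population (vectorised over sites).

    Returns ``(p, n_alleles)``; p is NaN where no genotype is called.
    """
    d = np.asarray(dosage_rows)
    called = d >= 0
    n_alleles = 2 * called.sum(axis=-1)
    alt = np.where(called, d, 0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return p, n_alleles


def observed_het(dosage_rows: np.ndarray):
    """Observed heterozygote proportion among called diploids per site."""
    d = np.asarray(dosage_rows)
    called = (d >= 0).sum(axis=-1)
    het = (d == 1).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / np.maximum(called, 1), np.nan)


def site_pi(p, n_alleles):
    """Unbiased per-site diversity (n/(n-1)) * 2p(1-p).

    Equals the mean pairwise difference over the n called allele copies;
    NaN where fewer than two copies are called.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = n / (n - 1.0) * 2.0 * p * (1.0 - p)
    return np.where(n >= 2, pi, np.nan)


def wc84_components(p1, p2, n1, n2, h1, h2):
    """Weir & Cockerham (1984) variance components for two populations.

    ``n1, n2`` are called diploid counts, ``p1, p2`` alt-allele
    frequencies and ``h1, h2`` observed heterozygote proportions,
    vectorised over sites. Returns (a, b, c); entries are NaN where the
    estimator is undefined (fewer than two diploids overall or a
    population entirely missing).
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    h1, h2 = np.asarray(h1, float), np.asarray(h2, float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (
            pbar * (1.0 - pbar) - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def hudson_components(p1, p2, n1, n2):
    """Hudson-style F_ST numerator/denominator per site.

    Numerator (p1-p2)^2 - p1(1-p1)/(m1-1) - p2(1-p2)/(m2-1) with m the
    allele-copy counts; denominator p1(1-p2) + p2(1-p1). NaN where either
    population has fewer than two copies.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    m1 = 2.0 * np.asarray(n1, float)
    m2 = 2.0 * np.asarray(n2, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (m1 - 1.0)
               - p2 * (1 - p2) / (m2 - 1.0))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (m1 < 2) | (m2 < 2)
    return np.where(bad, np.nan, num), np.where(bad, np.nan, den)


def window_fst(a, abc_sum):
    """Ratio-of-sums window F_ST: sum(a)/sum(a+b+c), clamped to [0, 1].

    Returns NaN when the denominator is zero (no informative sites)."""
    a_sum = float(np.nansum(a))
    d_sum = float(np.nansum(abc_sum))
    if d_sum == 0:
        return float("nan")
    return min(max(a_sum / d_sum, 0.0), 1.0)


def _window_sums(pos_0based, values, starts, ends):
    """Sum per-site ``values`` (NaN-ignored) into [start, end) windows via
    cumulative sums; sites must be sorted by position."""
    v = np.nan_to_num(np.asarray(values, float), nan=0.0)
    cum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.searchsorted(pos_0based, starts, side="left")
    hi = np.searchsorted(pos_0based, ends, side="left")
    return cum[hi] - cum[lo], lo, hi


def comparison_window_stats(matrix: GenotypeMatrix, ref_samples, test_samples,
                            config: WindowConfig = None,
                            comparison: str = "ref-vs-test") -> pd.DataFrame:
    """Per-window pi (both populations) and F_ST for one comparison.

    Returns a DataFrame with one row per window: chrom, start, end,
    truncated, n_sites (usable in both populations), pi_ref, pi_test, fst,
    eligible (enough sites for thresholding) and the comparison label.
    """
    config = config or WindowConfig()
    ref_idx = matrix.sample_indices(ref_samples)
    test_idx = matrix.sample_indices(test_samples)

    d_ref = matrix.dosage[:, ref_idx]
    d_test = matrix.dosage[:, test_idx]
    p1, m1 = site_freq(d_ref)
    p2, m2 = site_freq(d_test)
    h1 = observed_het(d_ref)
    h2 = observed_het(d_test)
    usable = (m1 >= 2) & (m2 >= 2)

    pi_ref = np.where(usable, site_pi(p1, m1), np.nan)
    pi_test = np.where(usable, site_pi(p2, m2), np.nan)
    if config.fst_estimator == "wc84":
        a, b, c = wc84_components(p1, p2, m1 / 2.0, m2 / 2.0, h1, h2)
        num = np.where(usable, a, np.nan)
        den = np.where(usable, a + b + c, np.nan)
    else:
        num, den = hudson_components(p1, p2, m1 / 2.0, m2 / 2.0)
        num = np.where(usable, num, np.nan)
        den = np.where(usable, den, np.nan)

    windows = make_windows(matrix.chrom_lengths, config.size, config.step)
    rows = []
    for chrom in matrix.chrom_lengths:
        w_chr = [w for w in windows if w.chrom == chrom]
        if not w_chr:
            continue
        sidx = matrix.sites_on(chrom)
        pos0 = matrix.pos[sidx] - 1  # site position as 0-based point
        starts = np.array([w.start for w in w_chr])
        ends = np.array([w.end for w in w_chr])
        pi_ref_sum, lo, hi = _window_sums(pos0, pi_ref[sidx], starts, ends)
        pi_test_sum, _, _ = _window_sums(pos0, pi_test[sidx], starts, ends)
        num_sum, _, _ = _window_sums(pos0, num[sidx], starts, ends)
        den_sum, _, _ = _window_sums(pos0, den[sidx], starts, ends)
        n_sites, _, _ = _window_sums(pos0, usable[sidx].astype(float), starts, ends)
        spans = (ends - starts).astype(float)
        denom = spans if config.pi_denominator == "span" else np.maximum(n_sites, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(den_sum != 0, np.clip(num_sum / np.where(
                den_sum != 0, den_sum, 1.0), 0.0, 1.0), np.nan)
        for k, w in enumerate(w_chr):
            rows.append((w.chrom, w.start, w.end, w.truncated,
                         int(n_sites[k]), pi_ref_sum[k] / denom[k],
                         pi_test_sum[k] / denom[k], fst[k]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "truncated",
                                     "n_sites", "pi_ref", "pi_test", "fst"])
    df["eligible"] = (df["n_sites"] >= config.min_sites) & df["fst"].notna()
    df["comparison"] = comparison
    return df


def window_pi(matrix: GenotypeMatrix, samples, config: WindowConfig = None) -> pd.DataFrame:
    """Per-window pi for a single population (chrom, start, end, n_sites, pi)."""
    config = config or WindowConfig()
    idx = matrix.sample_indices(samples)
    p, m = site_freq(matrix.dosage[:, idx])
    pi = site_pi(p, m)
    usable = m >= 2
    windows = make_windows(matrix.chrom_lengths, config.size, config.step)
    rows = []
    for chrom in matrix.chrom_lengths:
        w_chr = [w for w in windows if w.chrom == chrom]
        if not w_chr:
            continue
        sidx = matrix.sites_on(chrom)
        pos0 = matrix.pos[sidx] - 1
        starts = np.array([w.start for w in w_chr])
        ends = np.array([w.end for w in w_chr])
        pi_sum, _, _ = _window_sums(pos0, np.where(usable, pi, np.nan)[sidx], starts, ends)
        n_sites, _, _ = _window_sums(pos0, usable[sidx].astype(float), starts, ends)
        spans = (ends - starts).astype(float)
        denom = spans if config.pi_denominator == "span" else np.maximum(n_sites, 1)
        for k, w in enumerate(w_chr):
            rows.append((w.chrom, w.start, w.end, int(n_sites[k]), pi_sum[k] / denom[k]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi"])


def genome_pi(matrix: GenotypeMatrix, samples) -> float:
    """Genome-wide nucleotide diversity: sum of per-site diversities over
    the total genome length in bp."""
    idx = matrix.sample_indices(samples)
    p, m = site_freq(matrix.dosage[:, idx])
    pi = site_pi(p, m)
    total = float(sum(matrix.chrom_lengths.values()))
    return float(np.nansum(pi)) / total
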