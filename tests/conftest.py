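import numpy as np
import pytest

from sweepscan.model import MISSING, GenotypeMatrix


def make_matrix(dosage, positions=None, chrom="chr1", chrom_length=1_000_000,
                samples=None):
    """Build a small single-chromosome GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        dosage=dosage,
        samples=samples,
        chrom_lengths={chrom: chrom_length},
    )


def random_matrix(rng, n_sites=200, n_samples=10, missing_rate=0.05,
                  chrom_length=None):
    """Random matrix with uniform allele frequencies and missing cells."""
    p = rng.uniform(0.02, 0.98, size=n_sites)
    dosage = rng.binomial(2, p[:, None], size=(n_sites, n_samples)).astype(np.int8)
    dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    length = chrom_length or (n_sites * 100 + 1000)
    positions = np.sort(rng.choice(np.arange(1, length), size=n_sites,
                                   replace=False))
    return make_matrix(dosage, positions=positions, chrom_length=length)


def pairwise_pi_oracle(dosage_rows, span):
    """Brute-force window pi: mean pairwise difference over all 2N allele
    copies at each site (unphased copies: dosage d contributes d alt and
    2-d ref copies), summed over sites and divided by the span in bp.

    Deliberately enumerates every pair of copies rather than using any
    frequency formula.
    """
    total = 0.0
    for row in np.asarray(dosage_rows):
        copies = []
        for d in row:
            if d >= 0:
                copies.extend([1] * int(d) + [0] * (2 - int(d)))
        n = len(copies)
        if n < 2:
            continue
        diffs = pairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                pairs += 1
                diffs += copies[i] != copies[j]
        total += diffs / pairs
    return total / span


def wc84_oracle(p1, p2, n1, n2, h1, h2):
    """Independent scalar transcription of the Weir & Cockerham (1984)
    two-allele variance components for r sampled populations, specialised
    to r = 2 (n in diploids, p allele frequency, h observed het
    proportion)."""
    r = 2
    ns = [n1, n2]
    ps = [p1, p2]
    hs = [h1, h2]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n ** 2 for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    ssq = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (ssq - (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * ssq
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def hypergeom_tail_oracle(k, K, n, N):
    """P(X >= k) by explicit pmf summation with exact binomials."""
    from math import comb

    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def cluster_oracle(positions, window_bp=15, count=3):
    """Brute-force SNP-cluster flags: slide every possible inclusive
    window of window_bp over the chromosome; flag all SNPs of any window
    holding >= count SNPs."""
    pos = np.asarray(positions)
    flags = np.zeros(len(pos), dtype=bool)
    for start in range(int(pos.min()) - window_bp + 1, int(pos.max()) + 1):
        inside = (pos >= start) & (pos <= start + window_bp - 1)
        if inside.sum() >= count:
            flags |= inside
    return flags


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Small-but-complete simulation config shared across tests."""
    from sweepscan.simulate import SimConfig

    return SimConfig(
        seed=11,
        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
        snp_density=1 / 400,
        groups={"test": {"t1": 8}, "refA": {"a1": 8}, "refB": {"b1": 8}},
        sweeps=[("chr1", 600_000, 900_000), ("chr2", 1_200_000, 1_500_000)],
        n_cnvr=15,
        cnv_samples=8,
    )
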