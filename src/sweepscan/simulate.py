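"""Synthetic population generator with known ground truth.

Allele frequencies follow the Balding-Nichols model: each site draws an
ancestral frequency p0 ~ Uniform(0.05, 0.95) and each population draws
its frequency from Beta(p0(1-F)/F, (1-p0)(1-F)/F), whose expected
differentiation is approximately F. Genotypes are Binomial(2, p_pop) per
diploid. Inside implanted sweep intervals the test population's
frequency is pushed toward the nearer of {0, 1} by factor ``s_fst``
(raising differentiation) and sites are additionally collapsed to
monomorphic with probability ``s_pi`` (suppressing diversity) — the
frequency-level signature of a selective sweep, implanted directly so
that truth is exact rather than emerging from selection dynamics.

The default configuration mirrors the study design this pipeline serves:
one test breed of 12 diploids against three reference groups (4, 3 and 3
breeds of 10 diploids each), background F = 0.10, about one SNP per
500 bp on three 10-Mb chromosomes, and one 500-kb sweep per chromosome
at strengths s_pi = s_fst = 0.9.

All randomness derives from a single integer seed through fixed-offset
substreams, so identical configs give byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .model import MISSING, CNVCall, GeneModel, GenotypeMatrix, PopulationMap


def _default_chroms():
    return {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}


def _default_groups():
    return {
        "test": {"test_1": 12},
        "south": {"south_1": 10, "south_2": 10, "south_3": 10, "south_4": 10},
        "central": {"central_1": 10, "central_2": 10, "central_3": 10},
        "north": {"north_1": 10, "north_2": 10, "north_3": 10},
    }


def _default_sweeps():
    return [("chr1", 3_000_000, 3_500_000),
            ("chr2", 5_200_000, 5_700_000),
            ("chr3", 7_600_000, 8_100_000)]


@dataclass
class SimConfig:
    seed: int = 1
    chrom_lengths: dict = field(default_factory=_default_chroms)
    snp_density: float = 1 / 500  # variable sites per bp
    groups: dict = field(default_factory=_default_groups)  # group -> breed -> n
    test_group: str = "test"
    background_f: float = 0.10  # Balding-Nichols differentiation
    breed_f: float = 0.0  # extra within-group differentiation between breeds
    sweeps: list = field(default_factory=_default_sweeps)  # (chrom, start, end)
    s_pi: float = 0.9  # P(site collapses to monomorphic in the test group)
    s_fst: float = 0.9  # push of test-group frequency toward nearer boundary
    missing_rate: float = 0.02
    # CNV simulation
    n_cnvr: int = 40
    cnv_samples: int = 12
    cnv_jitter: int = 200  # bp trimmed randomly from each end of a call
    deletion_fraction: float = 0.75  # deletion:duplication ~ 3:1
    # gene/term simulation
    n_background_terms: int = 20

    def validate(self) -> None:
        if not (0 <= self.background_f < 1 and 0 <= self.breed_f < 1):
            raise ValueError("differentiation F must be in [0, 1)")
        if not (0 < self.s_pi <= 1):
            raise ValueError("s_pi must be in (0, 1]")
        if not (0 <= self.s_fst <= 1):
            raise ValueError("s_fst must be in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 < self.snp_density <= 0.1):
            raise ValueError("snp_density out of range")
        if self.test_group not in self.groups:
            raise ValueError(f"test_group {self.test_group!r} not in groups")
        by_chrom = {}
        for chrom, start, end in self.sweeps:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"sweep ({chrom}, {start}, {end}) outside chromosome")
            by_chrom.setdefault(chrom, []).append((start, end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    raise ValueError("sweep intervals overlap")


@dataclass
class SimTruth:
    sweeps: list  # (chrom, start, end) 0-based half-open
    ancestral_freq: np.ndarray = None  # per site
    group_freq: dict = None  # group -> per-site frequency (post-sweep)
    cnvr_truth: list = None  # (chrom, start, end)
    config: SimConfig = None


_STREAMS = ("positions", "frequencies", "sweeps", "genotypes", "missing",
            "genes", "terms", "cnv")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS.index(stream), config.seed])


def _draw_positions(rng, length, n):
    """n distinct sorted 1-based positions on a chromosome."""
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 16))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_populations(config: SimConfig = None):
    """Simulate genotypes for every breed under the Balding-Nichols model.

    Returns ``(GenotypeMatrix, PopulationMap, SimTruth)``.
    """
    config = config or SimConfig()
    config.validate()
    rng_pos = _rng(config, "positions")
    rng_freq = _rng(config, "frequencies")
    rng_sweep = _rng(config, "sweeps")
    rng_geno = _rng(config, "genotypes")
    rng_miss = _rng(config, "missing")

    chroms, positions = [], []
    for chrom, length in config.chrom_lengths.items():
        n = int(round(config.snp_density * length))
        pos = _draw_positions(rng_pos, length, n)
        chroms.extend([chrom] * n)
        positions.append(pos)
    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.concatenate(positions) if positions else np.array([], np.int64)
    n_sites = len(pos_arr)

    p0 = rng_freq.uniform(0.05, 0.95, size=n_sites)

    def balding_nichols(rng, base, f):
        if f <= 0:
            return base.copy()
        return rng.beta(base * (1 - f) / f, (1 - base) * (1 - f) / f)

    group_freq = {g: balding_nichols(rng_freq, p0, config.background_f)
                  for g in config.groups}

    # implant sweep signal into the test group's frequencies
    in_sweep = np.zeros(n_sites, dtype=bool)
    for chrom, start, end in config.sweeps:
        in_sweep |= (chrom_arr == chrom) & (pos_arr - 1 >= start) & (pos_arr - 1 < end)
    pt = group_freq[config.test_group]
    target = (pt[in_sweep] >= 0.5).astype(float)  # nearer boundary
    pushed = pt[in_sweep] + config.s_fst * (target - pt[in_sweep])
    mono = rng_sweep.random(in_sweep.sum()) < config.s_pi
    pushed[mono] = target[mono]
    pt[in_sweep] = pushed

    samples, breed_of = [], {}
    breed_to_group = {}
    dosage_cols = []
    for group, breeds in config.groups.items():
        for breed, n_ind in breeds.items():
            breed_to_group[breed] = group
            p_breed = balding_nichols(rng_freq, group_freq[group], config.breed_f)
            dosage_cols.append(
                rng_geno.binomial(2, p_breed[:, None], size=(n_sites, n_ind))
                .astype(np.int8))
            for i in range(1, n_ind + 1):
                sid = f"{breed}_s{i:02d}"
                samples.append(sid)
                breed_of[sid] = breed
    dosage = (np.concatenate(dosage_cols, axis=1) if dosage_cols
              else np.empty((n_sites, 0), np.int8))
    if config.missing_rate > 0 and dosage.size:
        dosage[rng_miss.random(dosage.shape) < config.missing_rate] = MISSING

    matrix = GenotypeMatrix(
        chrom=chrom_arr, pos=pos_arr,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        dosage=dosage, samples=samples,
        chrom_lengths=dict(config.chrom_lengths),
    )
    popmap = PopulationMap(breed_of, breed_to_group, config.test_group)
    truth = SimTruth(sweeps=list(config.sweeps), ancestral_freq=p0,
                     group_freq=group_freq, config=config)
    return matrix, popmap, truth


def simulate_gene_models(config: SimConfig = None, truth: SimTruth = None):
    """Tile non-overlapping genes along each chromosome and build a term
    map containing one sweep-linked term (genes inside sweep intervals)
    plus random background terms.

    Returns ``(gene_models, term_to_genes)``.
    """
    config = config or SimConfig()
    rng = _rng(config, "genes")
    genes = []
    k = 0
    for chrom, length in config.chrom_lengths.items():
        cursor = int(rng.integers(1_000, 20_000))
        while True:
            span = int(rng.integers(5_000, 30_000))
            if cursor + span > length:
                break
            k += 1
            gid = f"GENE{k:04d}"
            n_ex = int(rng.integers(2, 7))
            bounds = np.sort(rng.choice(np.arange(span), size=2 * n_ex, replace=False))
            exons = [(cursor + int(bounds[2 * j]), cursor + int(bounds[2 * j + 1]) + 1)
                     for j in range(n_ex)]
            exons[0] = (cursor, exons[0][1])
            exons[-1] = (exons[-1][0], cursor + span)
            genes.append(GeneModel(
                gene_id=gid, gene_name=gid, chrom=chrom, start=cursor,
                end=cursor + span, strand="+" if rng.random() < 0.5 else "-",
                exons=exons))
            cursor += span + int(rng.integers(10_000, 60_000))

    sweeps = truth.sweeps if truth is not None else config.sweeps
    swept = {g.gene_id for g in genes
             for (chrom, s, e) in sweeps
             if g.chrom == chrom and g.start < e and g.end > s}
    rng_t = _rng(config, "terms")
    term_to_genes = {"TERM_SWEEP": set(swept)}
    gene_ids = [g.gene_id for g in genes]
    for t in range(1, config.n_background_terms + 1):
        size = int(rng_t.integers(10, 51))
        members = rng_t.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        term_to_genes[f"TERM_BG{t:02d}"] = set(members.tolist())
    return genes, term_to_genes


def simulate_cnv_calls(config: SimConfig = None):
    """Place disjoint truth CNVRs, then emit per-sample calls jittered
    inside them. Returns ``(calls, cnvr_truth)`` with truth as
    (chrom, start, end) intervals.
    """
    config = config or SimConfig()
    rng = _rng(config, "cnv")
    sample_ids = [f"cnv_s{i:02d}" for i in range(1, config.cnv_samples + 1)]
    chrom_names = list(config.chrom_lengths)
    truth, calls = [], []
    # log-uniform lengths spanning the three length classes (2-300 kb)
    placed = {c: [] for c in chrom_names}
    attempts = 0
    while len(truth) < config.n_cnvr and attempts < config.n_cnvr * 50:
        attempts += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        length = int(10 ** rng.uniform(np.log10(2_000), np.log10(300_000)))
        L = config.chrom_lengths[chrom]
        if length + 2 >= L:
            continue
        start = int(rng.integers(0, L - length))
        end = start + length
        margin = 2 * config.cnv_jitter + 1  # keep regions unbridgeable by jitter
        if any(start < e + margin and end + margin > s for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        truth.append((chrom, start, end))
        u = rng.random()
        n_carriers = 1 if u < 0.55 else (2 if u < 0.66 else
                                         int(rng.integers(3, config.cnv_samples + 1)))
        carriers = rng.choice(sample_ids, size=n_carriers, replace=False)
        for s in carriers:
            trim_a = int(rng.integers(0, config.cnv_jitter + 1))
            trim_b = int(rng.integers(0, config.cnv_jitter + 1))
            a, b = start + trim_a, end - trim_b
            if b <= a:
                a, b = start, end
            ctype = ("deletion" if rng.random() < config.deletion_fraction
                     else "duplication")
            calls.append(CNVCall(sample=str(s), chrom=chrom, start=a, end=b,
                                 type=ctype))
    truth.sort()
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample))
    return calls, truth


def write_fixture(out_dir, matrix, popmap, truth, gene_models=None,
                  term_to_genes=None, cnv_calls=None, cnvr_truth=None):
    """Write the simulated dataset as on-disk fixture files.

    Emits ``sim.vcf``, ``popmap.tsv``, ``truth.json`` and, when provided,
    ``genes.gff3``, ``terms.tsv`` and ``cnv_calls.tsv``. Files are
    deterministic for a given config/seed.
    """
    from pathlib import Path

    from . import io as gio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_vcf(out / "sim.vcf", matrix)
    gio.write_population_map(out / "popmap.tsv", popmap)
    if gene_models is not None:
        gio.write_gff3(out / "genes.gff3", gene_models)
    if term_to_genes is not None:
        with open(out / "terms.tsv", "w") as fh:
            for term in sorted(term_to_genes):
                for gene in sorted(term_to_genes[term]):
                    fh.write(f"{gene}\t{term}\n")
    if cnv_calls is not None:
        gio.write_cnv_calls(out / "cnv_calls.tsv", cnv_calls)
    payload = {
        "sweeps": [[c, int(s), int(e)] for c, s, e in truth.sweeps],
        "cnvr_truth": ([[c, int(s), int(e)] for c, s, e in cnvr_truth]
                       if cnvr_truth is not None else None),
        "config": _config_dict(truth.config) if truth.config else None,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _config_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sweeps"] = [[c, int(s), int(e)] for c, s, e in d["sweeps"]]
    return d
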