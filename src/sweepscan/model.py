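"""Core in-memory data model shared by all pipeline stages.

Coordinate conventions: VCF positions are 1-based on input and output;
every internal interval (windows, loci, genes once loaded, CNV calls) is
0-based half-open. The conversion happens exactly once, in the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MISSING = -1  # dosage sentinel for an uncalled genotype


@dataclass
class VariantRecord:
    """One VCF record, independent of whether it enters the dosage matrix.

    ``variant_class`` is one of ``snp``, ``insertion``, ``deletion`` or
    ``multiallelic``; ``length_change`` is len(alt) - len(ref) in bp.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_class: str
    length_change: int = 0
    genotypes: Optional[np.ndarray] = None  # per-sample dosage, MISSING allowed
    site_annotations: dict = field(default_factory=dict)  # e.g. QD, FS, MQ
    per_sample_gq: Optional[np.ndarray] = None  # -1 where absent
    filter_flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def is_snp(self) -> bool:
        return self.variant_class == "snp"

    @property
    def is_indel(self) -> bool:
        return self.variant_class in ("insertion", "deletion")

    @property
    def passes_filters(self) -> bool:
        return not self.filter_flags

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class GenotypeMatrix:
    """Biallelic-SNP sites x samples alt-allele dosage matrix.

    ``dosage`` holds 0/1/2 with ``MISSING`` (-1) for uncalled genotypes.
    Sites are sorted by (chromosome order of ``chrom_lengths``, position).
    ``site_qd/fs/mq`` are per-site annotations (NaN when absent) and ``gq``
    is the per-genotype quality (-1 when absent); all optional.
    """

    chrom: np.ndarray  # per-site chromosome name (object dtype)
    pos: np.ndarray  # per-site 1-based position, int64
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray  # (n_sites, n_samples) int8
    samples: list
    chrom_lengths: dict

    site_qd: Optional[np.ndarray] = None
    site_fs: Optional[np.ndarray] = None
    site_mq: Optional[np.ndarray] = None
    gq: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        missing_chroms = set(np.unique(self.chrom)) - set(self.chrom_lengths)
        if missing_chroms:
            raise ValueError(
                "sites on chromosome(s) absent from chrom_lengths: "
                + ", ".join(sorted(missing_chroms))
            )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        unknown = [s for s in ids if s not in lookup]
        if unknown:
            raise KeyError(f"samples not in matrix: {unknown}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[:, idx],
            samples=list(ids),
            chrom_lengths=dict(self.chrom_lengths),
            site_qd=self.site_qd,
            site_fs=self.site_fs,
            site_mq=self.site_mq,
            gq=None if self.gq is None else self.gq[:, idx],
        )

    def sites_on(self, chrom: str) -> np.ndarray:
        return np.nonzero(self.chrom == chrom)[0]


@dataclass
class PopulationMap:
    """sample -> breed and breed -> group assignment.

    One group is the *test* group (the population scanned for sweeps);
    the others serve as reference groups.
    """

    sample_to_breed: dict
    breed_to_group: dict
    test_group: str

    def __post_init__(self) -> None:
        for breed in set(self.sample_to_breed.values()):
            if breed not in self.breed_to_group:
                raise ValueError(f"breed {breed!r} has no group assignment")

    @property
    def groups(self) -> list:
        seen = []
        for g in self.breed_to_group.values():
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def reference_groups(self) -> list:
        return [g for g in self.groups if g != self.test_group]

    def group_of(self, sample: str) -> str:
        return self.breed_to_group[self.sample_to_breed[sample]]

    def samples_in_group(self, group: str) -> list:
        return [s for s in self.sample_to_breed
                if self.breed_to_group[self.sample_to_breed[s]] == group]

    def samples_in_breed(self, breed: str) -> list:
        return [s for s, b in self.sample_to_breed.items() if b == breed]


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 0-based half-open after loading
    end: int
    strand: str
    exons: list = field(default_factory=list)  # list of (start, end)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for (s, e) in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int
    truncated: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class SweepLocus:
    """A merged run of dual-outlier windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    max_fst: float
    max_pi_ratio: float
    genes: list = field(default_factory=list)


@dataclass(frozen=True)
class CNVCall:
    sample: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    type: str  # "deletion" | "duplication"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNV call must have end > start")
        if self.type not in ("deletion", "duplication"):
            raise ValueError(f"unknown CNV type {self.type!r}")


@dataclass
class CNVRegion:
    chrom: str
    start: int
    end: int
    samples: list
    types: list

    @property
    def length(self) -> int:
        return self.end - self.start
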