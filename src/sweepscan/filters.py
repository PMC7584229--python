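"""Hard-filtering of variant sites and descriptive variant summaries.

The site filters mirror GATK VariantFiltration semantics: a rule fires
only when its annotation is present and the failing expression is true
(QD < 4.0, FS > 50.0, MQ < 40.0); genotypes with GQ < 20 are masked to
missing; and SNPs packed 3-or-more into any 15-bp span are flagged as
clusters. Summaries cover substitution spectra (Ts/Tv), per-sample
homozygote/heterozygote counts, novelty against a known-variant set, and
region / InDel classification against gene models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
MAX_INDEL_BP = 50  # retention rule: InDels longer than this are rejected


@dataclass
class FilterConfig:
    qd_min: float = 4.0
    fs_max: float = 50.0
    mq_min: float = 40.0
    gq_min: int = 20
    cluster_window_bp: int = 15
    cluster_count: int = 3
    # whether cluster-flagged SNPs are removed before window statistics or
    # only annotated (the scan is exposed both ways)
    drop_clustered: bool = True

    def __post_init__(self) -> None:
        if min(self.qd_min, self.fs_max, self.mq_min, self.gq_min) <= 0:
            raise ValueError("all filter thresholds must be positive")
        if self.cluster_count < 2:
            raise ValueError("cluster_count must be >= 2")


def apply_hard_filters(records, config: FilterConfig):
    """Flag failing sites and mask low-GQ genotypes, in place.

    Site-level: fail on QD < qd_min, FS > fs_max or MQ < mq_min; a missing
    annotation means the corresponding rule is not applied (logged once).
    Genotype-level: any genotype with GQ < gq_min is set missing. Records
    are never deleted; flags accumulate in ``filter_flags``.
    """
    absent_logged = set()
    for rec in records:
        ann = rec.site_annotations
        for key, bad in (("QD", lambda v: v < config.qd_min),
                         ("FS", lambda v: v > config.fs_max),
                         ("MQ", lambda v: v < config.mq_min)):
            if key not in ann:
                if key not in absent_logged:
                    log.info("annotation %s absent on some sites; rule skipped there", key)
                    absent_logged.add(key)
                continue
            if bad(ann[key]) and key not in rec.filter_flags:
                rec.filter_flags.append(key)
        if rec.per_sample_gq is not None and rec.genotypes is not None:
            low = (rec.per_sample_gq >= 0) & (rec.per_sample_gq < config.gq_min)
            rec.genotypes[low] = MISSING
    return records


def site_pass_mask(matrix: GenotypeMatrix, config: FilterConfig) -> np.ndarray:
    """Vectorised site-level QD/FS/MQ filter over a GenotypeMatrix."""
    keep = np.ones(matrix.n_sites, dtype=bool)
    if matrix.site_qd is not None:
        keep &= ~(matrix.site_qd < config.qd_min)  # NaN compares False: rule skipped
    if matrix.site_fs is not None:
        keep &= ~(matrix.site_fs > config.fs_max)
    if matrix.site_mq is not None:
        keep &= ~(matrix.site_mq < config.mq_min)
    return keep


def mask_low_gq(matrix: GenotypeMatrix, config: FilterConfig) -> GenotypeMatrix:
    """Set genotypes with GQ < gq_min to missing (returns the same matrix)."""
    if matrix.gq is not None:
        low = (matrix.gq >= 0) & (matrix.gq < config.gq_min)
        matrix.dosage[low] = MISSING
    return matrix


def flag_snp_clusters(positions, config: FilterConfig) -> np.ndarray:
    """Flag SNPs lying in clusters: >= cluster_count SNPs within any
    inclusive span of cluster_window_bp on one chromosome.

    ``positions`` must be strictly increasing. Returns a boolean array.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing on one chromosome")
    n = len(pos)
    flags = np.zeros(n, dtype=bool)
    j = 0
    for i in range(n):
        # widest run starting at i fitting in the inclusive window span
        j = max(j, i)
        while j + 1 < n and pos[j + 1] - pos[i] + 1 <= config.cluster_window_bp:
            j += 1
        if j - i + 1 >= config.cluster_count:
            flags[i:j + 1] = True
    return flags


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as transition or transversion."""
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT base in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return "transition" if (ref, alt) in TRANSITIONS else "transversion"


def substitution_spectrum(refs, alts) -> pd.DataFrame:
    """Count the 12 ordered ref->alt substitution types plus Ts/Tv totals."""
    pairs = [f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a]
    counts = {p: 0 for p in pairs}
    for r, a in zip(refs, alts):
        counts[f"{r}>{a}"] += 1
    df = pd.DataFrame({"substitution": pairs, "count": [counts[p] for p in pairs]})
    df["class"] = [classify_substitution(*p.split(">")) for p in pairs]
    return df


def ts_tv_ratio(refs, alts) -> float:
    classes = [classify_substitution(r, a) for r, a in zip(refs, alts)]
    ts = sum(c == "transition" for c in classes)
    tv = len(classes) - ts
    return ts / tv if tv else float("inf")


def summarize_genotypes(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample counts of heterozygous (dosage 1) and homozygous-alt
    (dosage 2) genotypes; homozygous-ref and missing count in neither."""
    het = (matrix.dosage == 1).sum(axis=0)
    hom = (matrix.dosage == 2).sum(axis=0)
    return pd.DataFrame({"sample": matrix.samples, "het": het, "hom_alt": hom})


def classify_novelty(records, known_set) -> list:
    """Label each record known/novel by exact (chrom, pos, ref, alt) match.

    A site at a known position but with mismatched alleles counts novel.
    """
    return ["known" if rec.key() in known_set else "novel" for rec in records]


class _GeneIndex:
    """Interval lookups for gene bodies and exons on each chromosome."""

    def __init__(self, gene_models):
        from intervaltree import IntervalTree

        self.gene_trees, self.exon_trees = {}, {}
        for g in gene_models:
            self.gene_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id)
            for (s, e) in g.exons:
                self.exon_trees.setdefault(g.chrom, IntervalTree()).addi(
                    s, e, g.gene_id)

    def region_of(self, chrom: str, pos: int) -> str:
        """Classify a 1-based position as exonic / intronic / intergenic."""
        p = pos - 1  # to 0-based point
        if chrom in self.exon_trees and self.exon_trees[chrom].at(p):
            return "exonic"
        if chrom in self.gene_trees and self.gene_trees[chrom].at(p):
            return "intronic"
        return "intergenic"


def classify_region(records, gene_models) -> list:
    """Classify each record's position against gene models."""
    index = _GeneIndex(gene_models)
    return [index.region_of(rec.chrom, rec.pos) for rec in records]


def classify_indel(record, gene_models) -> str:
    """Classify an InDel record.

    Exonic InDels are frameshift iff |length change| is not a multiple of
    3, crossed with insertion/deletion; non-exonic InDels are labelled by
    their region class. InDels longer than 50 bp are rejected.
    """
    if not record.is_indel:
        raise ValueError("record is not an InDel")
    if abs(record.length_change) > MAX_INDEL_BP:
        raise ValueError(
            f"InDel of {abs(record.length_change)} bp exceeds the "
            f"{MAX_INDEL_BP}-bp retention limit")
    index = gene_models if isinstance(gene_models, _GeneIndex) else _GeneIndex(gene_models)
    region = index.region_of(record.chrom, record.pos)
    if region != "exonic":
        return f"{region} {record.variant_class}"
    frame = "non-frameshift" if abs(record.length_change) % 3 == 0 else "frameshift"
    return f"{frame} {record.variant_class}"


def variant_summary_tables(matrix, records, gene_models=None, known_set=None):
    """Assemble the descriptive summary tables for a call set.

    Returns a dict of DataFrames: substitution spectrum + Ts/Tv, per-sample
    hom/het, and (when inputs allow) novelty, region classes and InDel
    classes.
    """
    snps = [r for r in records if r.is_snp]
    out = {
        "substitutions": substitution_spectrum(
            [r.ref_allele for r in snps], [r.alt_allele for r in snps]),
        "genotypes": summarize_genotypes(matrix),
    }
    out["ts_tv"] = pd.DataFrame({
        "metric": ["transitions", "transversions", "ts_tv_ratio"],
        "value": [
            int(out["substitutions"].query("`class`=='transition'")["count"].sum()),
            int(out["substitutions"].query("`class`=='transversion'")["count"].sum()),
            ts_tv_ratio([r.ref_allele for r in snps], [r.alt_allele for r in snps])
            if snps else float("nan"),
        ],
    })
    if known_set is not None:
        novelty = classify_novelty(snps, known_set)
        out["novelty"] = pd.DataFrame({
            "class": ["known", "novel"],
            "count": [novelty.count("known"), novelty.count("novel")],
        })
    if gene_models is not None:
        regions = classify_region(snps, gene_models)
        out["regions"] = pd.DataFrame({
            "class": ["exonic", "intronic", "intergenic"],
            "count": [regions.count(c) for c in ("exonic", "intronic", "intergenic")],
        })
        indels = [r for r in records
                  if r.is_indel and abs(r.length_change) <= MAX_INDEL_BP]
        index = _GeneIndex(gene_models)
        classes = [classify_indel(r, index) for r in indels]
        out["indel_classes"] = (
            pd.Series(classes, dtype=object).value_counts().rename_axis("class")
            .reset_index(name="count"))
    return out
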