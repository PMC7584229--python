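"""Readers and writers for the standard formats the pipeline touches.

VCF is read with cyvcf2 and written with pysam (round-trip through two
independent htslib bindings doubles as a format sanity check in the test
suite). GFF3 gene models are loaded through gffutils. Positions are 1-based
in VCF, converted here to the package-internal 0-based half-open intervals
for genes; BED output is 0-based half-open as the format demands.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .model import MISSING, GeneModel, GenotypeMatrix, PopulationMap, VariantRecord

log = logging.getLogger(__name__)

_SITE_ANN_KEYS = ("QD", "FS", "MQ")


def _classify_alleles(ref: str, alt: str) -> tuple:
    """Return (variant_class, length_change) for a single ALT allele."""
    if "," in alt:
        return "multiallelic", 0
    delta = len(alt) - len(ref)
    if len(ref) == 1 and len(alt) == 1:
        return "snp", 0
    if delta > 0:
        return "insertion", delta
    if delta < 0:
        return "deletion", delta
    return "mnp", 0


def read_vcf(path, sample_subset=None):
    """Read a VCF into a :class:`GenotypeMatrix` plus a full record list.

    Only biallelic SNPs populate the matrix; InDels, multiallelic and other
    sites are returned as :class:`VariantRecord` entries flagged by class.
    Chromosome lengths come from ``##contig`` header lines; a record on a
    contig absent from the header is an error.

    Returns ``(matrix, records)``.
    """
    vcf = VCF(str(path), gts012=True, samples=list(sample_subset) if sample_subset else None)
    if "GT" not in [f["ID"] for f in _format_headers(vcf)]:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    try:
        chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:
        chrom_lengths = {}

    records = []
    m_chrom, m_pos, m_ref, m_alt = [], [], [], []
    m_dos, m_gq = [], []
    m_qd, m_fs, m_mq = [], [], []
    for v in vcf:
        if v.CHROM not in chrom_lengths:
            raise ValueError(
                f"{path}: contig {v.CHROM!r} missing from ##contig headers"
            )
        alt = ",".join(v.ALT) if v.ALT else "."
        vclass, delta = _classify_alleles(v.REF, alt)
        dosage = np.asarray(v.gt_types, dtype=np.int8)
        dosage[dosage == 3] = MISSING  # cyvcf2 UNKNOWN
        ann = {k: float(v.INFO.get(k)) for k in _SITE_ANN_KEYS if v.INFO.get(k) is not None}
        gq = None
        try:
            raw_gq = v.format("GQ")
        except KeyError:
            raw_gq = None
        if raw_gq is not None:
            gq = np.asarray(raw_gq, dtype=np.int32).reshape(-1)
            gq[gq < 0] = -1
        rec = VariantRecord(
            chrom=v.CHROM, pos=v.POS, ref_allele=v.REF.upper(),
            alt_allele=alt.upper(), variant_class=vclass, length_change=delta,
            genotypes=dosage, site_annotations=ann, per_sample_gq=gq,
        )
        records.append(rec)
        if vclass == "snp":
            m_chrom.append(v.CHROM)
            m_pos.append(v.POS)
            m_ref.append(rec.ref_allele)
            m_alt.append(rec.alt_allele)
            m_dos.append(dosage)
            m_gq.append(gq if gq is not None else np.full(len(samples), -1, np.int32))
            m_qd.append(ann.get("QD", np.nan))
            m_fs.append(ann.get("FS", np.nan))
            m_mq.append(ann.get("MQ", np.nan))

    n = len(m_pos)
    matrix = GenotypeMatrix(
        chrom=np.array(m_chrom, dtype=object),
        pos=np.array(m_pos, dtype=np.int64),
        ref=np.array(m_ref, dtype=object),
        alt=np.array(m_alt, dtype=object),
        dosage=(np.vstack(m_dos) if n else np.empty((0, len(samples)), np.int8)),
        samples=samples,
        chrom_lengths=chrom_lengths,
        site_qd=np.array(m_qd), site_fs=np.array(m_fs), site_mq=np.array(m_mq),
        gq=(np.vstack(m_gq) if n else np.empty((0, len(samples)), np.int32)),
    )
    return matrix, records


def _format_headers(vcf):
    for h in vcf.header_iter():
        info = h.info()
        if info.get("HeaderType") == "FORMAT":
            yield info


def write_vcf(path, matrix: GenotypeMatrix) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 file (via pysam)."""
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in matrix.chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.samples:
        header.add_sample(s)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(matrix.n_sites):
            rec = out.new_record(
                contig=str(matrix.chrom[i]),
                start=int(matrix.pos[i]) - 1,
                alleles=(str(matrix.ref[i]), str(matrix.alt[i])),
            )
            for j, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_of[int(matrix.dosage[i, j])]
                rec.samples[s].phased = False
            out.write(rec)


def merge_group_snps(matrices) -> GenotypeMatrix:
    """Merge per-breed matrices into one group matrix (site-set union).

    Samples are concatenated; a sample whose breed matrix lacks a union
    site is missing there. Conflicting ref/alt at the same position is an
    error naming the offending site(s).
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    ref_cl = matrices[0].chrom_lengths
    for m in matrices[1:]:
        if m.chrom_lengths != ref_cl:
            raise ValueError("matrices disagree on chrom_lengths")
    all_samples = [s for m in matrices for s in m.samples]
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("sample IDs overlap between matrices")

    # union of sites keyed by (chrom, pos), checking allele consistency
    alleles = {}
    conflicts = []
    for m in matrices:
        for i in range(m.n_sites):
            key = (m.chrom[i], int(m.pos[i]))
            al = (m.ref[i], m.alt[i])
            if key in alleles and alleles[key] != al:
                conflicts.append(key)
            alleles.setdefault(key, al)
    if conflicts:
        raise ValueError(f"conflicting ref/alt at sites: {sorted(set(conflicts))}")

    chrom_order = {c: k for k, c in enumerate(ref_cl)}
    keys = sorted(alleles, key=lambda k: (chrom_order[k[0]], k[1]))
    row_of = {k: i for i, k in enumerate(keys)}
    dosage = np.full((len(keys), len(all_samples)), MISSING, dtype=np.int8)
    col = 0
    for m in matrices:
        rows = np.array([row_of[(m.chrom[i], int(m.pos[i]))] for i in range(m.n_sites)],
                        dtype=np.intp)
        dosage[rows, col:col + m.n_samples] = m.dosage
        col += m.n_samples
    return GenotypeMatrix(
        chrom=np.array([k[0] for k in keys], dtype=object),
        pos=np.array([k[1] for k in keys], dtype=np.int64),
        ref=np.array([alleles[k][0] for k in keys], dtype=object),
        alt=np.array([alleles[k][1] for k in keys], dtype=object),
        dosage=dosage,
        samples=all_samples,
        chrom_lengths=dict(ref_cl),
    )


def read_gff_genes(path):
    """Load gene models (with exon intervals) from a GFF3 file.

    Coordinates are converted to 0-based half-open. Exons attach to their
    gene through the Parent chain (exon -> mRNA -> gene or exon -> gene);
    an exon whose parent cannot be resolved is dropped with a warning.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = {}
    order = []
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", [g.id])[0]
        genes[g.id] = GeneModel(
            gene_id=g.id, gene_name=name, chrom=g.seqid,
            start=g.start - 1, end=g.end, strand=g.strand, exons=[],
        )
        order.append(g.id)
    for ex in db.features_of_type("exon"):
        gene_id = _resolve_gene_parent(db, ex)
        if gene_id is None or gene_id not in genes:
            log.warning("exon %s has no resolvable gene parent; dropped", ex.id)
            continue
        genes[gene_id].exons.append((ex.start - 1, ex.end))
    for g in genes.values():
        g.exons.sort()
    return [genes[i] for i in order]


def _resolve_gene_parent(db, feature, depth=0):
    if depth > 5:
        return None
    for pid in feature.attributes.get("Parent", []):
        try:
            parent = db[pid]
        except Exception:
            return None
        if parent.featuretype == "gene":
            return parent.id
        resolved = _resolve_gene_parent(db, parent, depth + 1)
        if resolved:
            return resolved
    return None


def read_population_map(path, test_group: str) -> PopulationMap:
    """Read a ``sample<TAB>breed<TAB>group`` TSV into a PopulationMap."""
    sample_to_breed, breed_to_group = {}, {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated columns")
            sample, breed, group = parts
            sample_to_breed[sample] = breed
            if breed in breed_to_group and breed_to_group[breed] != group:
                raise ValueError(f"{path}: breed {breed!r} mapped to two groups")
            breed_to_group[breed] = group
    return PopulationMap(sample_to_breed, breed_to_group, test_group)


def write_population_map(path, popmap: PopulationMap) -> None:
    with open(path, "w") as fh:
        for sample, breed in popmap.sample_to_breed.items():
            fh.write(f"{sample}\t{breed}\t{popmap.breed_to_group[breed]}\n")


def write_bed(path, intervals, extra_columns=None) -> None:
    """Write (chrom, start, end) triples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            row = [str(chrom), str(int(start)), str(int(end))]
            if extra_columns is not None:
                row.extend(str(x) for x in extra_columns[i])
            fh.write("\t".join(row) + "\n")


def write_gff3(path, gene_models) -> None:
    """Write gene models (and their exons) as GFF3 (fixture output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            attrs = f"ID={g.gene_id};Name={g.gene_name}"
            fh.write(f"{g.chrom}\tsweepscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tsweepscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n")


def read_term_map(path):
    """Read a two-column ``gene<TAB>term`` TSV into term -> set(genes)."""
    terms = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected gene<TAB>term")
            gene, term = parts[0], parts[1]
            terms.setdefault(term, set()).add(gene)
    return terms


def read_cnv_calls(path):
    """Read BED-like CNV calls: chrom, start, end, sample, type (TSV)."""
    from .model import CNVCall

    calls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 columns "
                                 "(chrom, start, end, sample, type)")
            chrom, start, end, sample, ctype = parts
            calls.append(CNVCall(sample=sample, chrom=chrom, start=int(start),
                                 end=int(end), type=ctype))
    return calls


def write_cnv_calls(path, calls) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample}\t{c.type}\n")
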