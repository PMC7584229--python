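"""End-to-end orchestration: simulate -> window stats -> sweep scan ->
gene assignment -> shared loci -> enrichment -> report directory.

A run is driven by a single declarative YAML config (CLI flags override
individual keys). Every output is a TSV/BED/JSON file in the report
directory plus a deterministic ``manifest.json`` (config echo, input
digests, thresholds, counts, seed, version) whose SHA-256 digest is
stable across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import enrich as enrich_mod
from . import io as gio
from . import sweep as sweep_mod
from .cnv import cnvr_summary, merge_cnv_calls
from .filters import FilterConfig, flag_snp_clusters, mask_low_gq, site_pass_mask
from .simulate import SimConfig, simulate_cnv_calls, simulate_gene_models, \
    simulate_populations, write_fixture
from .windows import WindowConfig, comparison_window_stats, genome_pi

log = logging.getLogger(__name__)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d or {})
    if "sweeps" in d:
        d["sweeps"] = [tuple(s) for s in d["sweeps"]]
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulate config keys: {sorted(unknown)}")
    return SimConfig(**d)


def window_config_from_dict(d: dict) -> WindowConfig:
    return WindowConfig(**(d or {}))


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def apply_snp_filters(matrix, filter_config: FilterConfig):
    """Site QD/FS/MQ filter, GQ masking and SNP-cluster handling on a
    GenotypeMatrix; returns the filtered matrix."""
    mask_low_gq(matrix, filter_config)
    keep = site_pass_mask(matrix, filter_config)
    if filter_config.drop_clustered:
        cluster = np.zeros(matrix.n_sites, dtype=bool)
        for chrom in matrix.chrom_lengths:
            idx = matrix.sites_on(chrom)
            if len(idx):
                cluster[idx] = flag_snp_clusters(matrix.pos[idx], filter_config)
        keep &= ~cluster
    if keep.all():
        return matrix
    from .model import GenotypeMatrix
    return GenotypeMatrix(
        chrom=matrix.chrom[keep], pos=matrix.pos[keep], ref=matrix.ref[keep],
        alt=matrix.alt[keep], dosage=matrix.dosage[keep], samples=matrix.samples,
        chrom_lengths=dict(matrix.chrom_lengths),
        site_qd=None if matrix.site_qd is None else matrix.site_qd[keep],
        site_fs=None if matrix.site_fs is None else matrix.site_fs[keep],
        site_mq=None if matrix.site_mq is None else matrix.site_mq[keep],
        gq=None if matrix.gq is None else matrix.gq[keep],
    )


def run_sweep_pipeline(config, out_dir) -> dict:
    """Run the full scan described by ``config`` (dict or YAML path).

    Config keys: ``seed``; either ``simulate`` (SimConfig fields) or
    ``inputs`` (vcf, popmap, gff, terms, cnv_calls, test_group);
    ``window`` (size/step/min_sites/fst_estimator); ``quantile``
    (default 0.95); ``enrichment: true|false``. Writes per-comparison
    window TSVs, locus BED+TSV, shared-locus tables, Venn counts,
    optional enrichment TSVs and ``manifest.json``; returns the manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    q = float(config.get("quantile", sweep_mod.DEFAULT_QUANTILE))
    wcfg = window_config_from_dict(config.get("window"))
    input_digests = {}
    gene_models = term_map = None

    if "inputs" in config:
        inputs = config["inputs"]
        matrix, _records = gio.read_vcf(inputs["vcf"])
        popmap = gio.read_population_map(inputs["popmap"], inputs["test_group"])
        input_digests["vcf"] = _file_digest(inputs["vcf"])
        input_digests["popmap"] = _file_digest(inputs["popmap"])
        if inputs.get("gff"):
            gene_models = gio.read_gff_genes(inputs["gff"])
            input_digests["gff"] = _file_digest(inputs["gff"])
        else:
            log.warning("no GFF provided; gene columns will be empty")
        if inputs.get("terms"):
            term_map = gio.read_term_map(inputs["terms"])
            input_digests["terms"] = _file_digest(inputs["terms"])
        truth = None
    else:
        scfg = sim_config_from_dict(config.get("simulate"))
        if "seed" in config:
            scfg.seed = int(config["seed"])
        matrix, popmap, truth = simulate_populations(scfg)
        gene_models, term_map = simulate_gene_models(scfg, truth)

    if config.get("filters"):
        fcfg = FilterConfig(**config["filters"])
        matrix = apply_snp_filters(matrix, fcfg)

    comparisons = config.get("comparisons")
    if not comparisons:
        comparisons = [{"reference": g, "test": popmap.test_group}
                       for g in popmap.reference_groups]

    results = []
    for comp in comparisons:
        ref_g, test_g = comp["reference"], comp["test"]
        label = f"{ref_g}-vs-{test_g}"
        stats = comparison_window_stats(
            matrix, popmap.samples_in_group(ref_g),
            popmap.samples_in_group(test_g), wcfg, comparison=label)
        res = sweep_mod.scan_comparison(stats, q=q, gene_models=gene_models,
                                        comparison=label)
        results.append(res)
        res.stats.to_csv(out / f"windows.{label}.tsv", sep="\t", index=False,
                         float_format="%.6g")
        _write_loci(out, label, res.loci)

    shared_windows, shared, shared_genes = sweep_mod.shared_loci(
        results, gene_models=gene_models) if len(results) >= 2 else \
        (results[0].outlier_windows, results[0].loci, results[0].genes)
    _write_loci(out, "shared", shared)
    sweep_mod.venn_counts(results).to_csv(out / "venn_windows.tsv", sep="\t",
                                          index=False)

    group_pi = {g: genome_pi(matrix, popmap.samples_in_group(g))
                for g in popmap.groups}
    pd.DataFrame(sorted(group_pi.items()), columns=["group", "pi"]).to_csv(
        out / "group_pi.tsv", sep="\t", index=False, float_format="%.6g")

    enrichment_sig = {}
    if config.get("enrichment", True) and term_map and gene_models:
        background = [g.gene_id for g in gene_models]
        for res in results + [None]:
            genes = shared_genes if res is None else res.genes
            label = "shared" if res is None else res.comparison
            if not genes:
                continue
            tests = enrich_mod.hypergeom_enrich(genes, term_map, background)
            tests.to_csv(out / f"enrichment.{label}.tsv", sep="\t", index=False,
                         float_format="%.6g")
            enrichment_sig[label] = int(len(enrich_mod.filter_significant(tests)))

    manifest = {
        "tool": "sweepscan",
        "version": __version__,
        "seed": config.get("seed", config.get("simulate", {}).get("seed")),
        "config": _jsonable(config),
        "input_digests": input_digests,
        "comparisons": {
            r.comparison: {
                "t_fst": round(r.t_fst, 10),
                "t_pi_ratio": round(r.t_ratio, 10),
                "n_windows": int(len(r.stats)),
                "n_eligible": int(r.stats["eligible"].sum()),
                "n_outlier_windows": int(r.stats["outlier"].sum()),
                "n_loci": len(r.loci),
                "n_genes": len(r.genes),
            } for r in results
        },
        "shared": {"n_windows": int(len(shared_windows)),
                   "n_loci": len(shared), "n_genes": len(shared_genes)},
        "group_pi": {g: round(v, 10) for g, v in group_pi.items()},
        "n_significant_terms": enrichment_sig,
        "truth_sweeps": ([[c, int(s), int(e)] for c, s, e in truth.sweeps]
                         if truth else None),
    }
    text = json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    manifest["manifest_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_loci(out: Path, label: str, loci) -> None:
    rows = [(l.chrom, l.start, l.end, l.n_windows, l.max_fst, l.max_pi_ratio,
             ";".join(l.genes)) for l in loci]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows",
                                     "max_fst", "max_pi_ratio", "genes"])
    df.to_csv(out / f"loci.{label}.tsv", sep="\t", index=False,
              float_format="%.6g")
    gio.write_bed(out / f"loci.{label}.bed",
                  [(l.chrom, l.start, l.end) for l in loci])


def run_variant_summary(config, out_dir) -> dict:
    """Descriptive variant summary tables for a VCF (plus optional gene
    models, known-variant set and CNV calls)."""
    from .filters import variant_summary_tables

    if not isinstance(config, dict):
        config = load_config(config)
    inputs = config["inputs"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, records = gio.read_vcf(inputs["vcf"])
    gene_models = gio.read_gff_genes(inputs["gff"]) if inputs.get("gff") else None
    known = None
    if inputs.get("known_vcf"):
        _, known_records = gio.read_vcf(inputs["known_vcf"])
        known = {r.key() for r in known_records}
    tables = variant_summary_tables(matrix, records, gene_models, known)
    for name, df in tables.items():
        df.to_csv(out / f"summary.{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")
    if inputs.get("cnv_calls"):
        calls = gio.read_cnv_calls(inputs["cnv_calls"])
        regions = merge_cnv_calls(calls)
        cnvr_summary(regions).to_csv(out / "summary.cnvr.tsv", sep="\t",
                                     index=False, float_format="%.6g")
        gio.write_bed(out / "cnvr.bed",
                      [(r.chrom, r.start, r.end) for r in regions],
                      extra_columns=[(len(r.samples), ",".join(r.types))
                                     for r in regions])
    else:
        log.info("no CNV calls provided; CNVR section skipped")
    return {name: len(df) for name, df in tables.items()}


def run_simulate(config, out_dir) -> Path:
    """Simulate a full fixture dataset and write it to ``out_dir``."""
    if not isinstance(config, dict):
        config = load_config(config)
    scfg = sim_config_from_dict(config.get("simulate"))
    if "seed" in config:
        scfg.seed = int(config["seed"])
    matrix, popmap, truth = simulate_populations(scfg)
    genes, terms = simulate_gene_models(scfg, truth)
    calls, cnvr_truth = simulate_cnv_calls(scfg)
    return write_fixture(out_dir, matrix, popmap, truth, gene_models=genes,
                         term_to_genes=terms, cnv_calls=calls,
                         cnvr_truth=cnvr_truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
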