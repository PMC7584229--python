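"""Copy-number variable regions (CNVRs).

Per-individual CNV calls overlapping by at least 1 bp on a chromosome
(regardless of sample or deletion/duplication type) merge transitively
into a CNVR spanning their union. Abutting-but-not-overlapping calls stay
separate. CNVRs are classified by length (< 10 kb strict, 10-100 kb
inclusive, > 100 kb strict) and by how many individuals contribute
(unique / two / three-plus).
"""

from __future__ import annotations

import pandas as pd

from .model import CNVRegion

LENGTH_CLASSES = ("<10kb", "10-100kb", ">100kb")
SHARING_CLASSES = ("unique", "two", "three-plus")


def merge_cnv_calls(calls, by_type: bool = False):
    """Merge overlapping calls into CNVRs (transitive, >= 1 bp overlap).

    With ``by_type`` deletions and duplications are merged separately.
    Returns CNVRegions sorted by (chrom, start); regions are pairwise
    disjoint within each merge stratum.
    """
    def _merge(subset):
        regions = []
        by_chrom = {}
        for c in subset:
            by_chrom.setdefault(c.chrom, []).append(c)
        for chrom in sorted(by_chrom):
            cur_start = cur_end = None
            members = []
            for call in sorted(by_chrom[chrom], key=lambda c: (c.start, c.end)):
                if cur_end is not None and call.start < cur_end:  # >=1bp overlap
                    cur_end = max(cur_end, call.end)
                    members.append(call)
                else:
                    if members:
                        regions.append(_region(chrom, cur_start, cur_end, members))
                    cur_start, cur_end, members = call.start, call.end, [call]
            if members:
                regions.append(_region(chrom, cur_start, cur_end, members))
        return regions

    if by_type:
        out = (_merge([c for c in calls if c.type == "deletion"])
               + _merge([c for c in calls if c.type == "duplication"]))
        return sorted(out, key=lambda r: (r.chrom, r.start, r.end))
    return _merge(calls)


def _region(chrom, start, end, members) -> CNVRegion:
    return CNVRegion(chrom=chrom, start=start, end=end,
                     samples=sorted({c.sample for c in members}),
                     types=sorted({c.type for c in members}))


def classify_cnvr(region: CNVRegion):
    """Return ``(length_class, sharing_class)`` for a merged CNVR."""
    length = region.length
    if length < 10_000:
        length_class = "<10kb"
    elif length > 100_000:
        length_class = ">100kb"
    else:
        length_class = "10-100kb"
    n = len(region.samples)
    sharing_class = "unique" if n == 1 else ("two" if n == 2 else "three-plus")
    return length_class, sharing_class


def cnvr_summary(regions) -> pd.DataFrame:
    """Class-count table over merged CNVRs (length and sharing classes)."""
    rows = []
    classes = [classify_cnvr(r) for r in regions]
    for lc in LENGTH_CLASSES:
        rows.append(("length", lc, sum(c[0] == lc for c in classes)))
    for sc in SHARING_CLASSES:
        rows.append(("sharing", sc, sum(c[1] == sc for c in classes)))
    rows.append(("total", "all", len(regions)))
    df = pd.DataFrame(rows, columns=["dimension", "class", "count"])
    total = max(len(regions), 1)
    df["fraction"] = [c / total if d != "total" else 1.0
                      for d, _, c in df.itertuples(index=False)]
    return df
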