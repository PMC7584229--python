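import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan import filters as flt
from sweepscan.model import MISSING, GeneModel, VariantRecord

from conftest import cluster_oracle, make_matrix


def snp(pos=100, ref="A", alt="G", **kw):
    return VariantRecord(chrom="chr1", pos=pos, ref_allele=ref, alt_allele=alt,
                         variant_class="snp", **kw)


class TestHardFilters:
    @pytest.mark.parametrize("ann,expected_flags", [
        ({"QD": 3.9, "FS": 10, "MQ": 50}, ["QD"]),
        ({"QD": 10, "FS": 10, "MQ": 50}, []),
        ({"QD": 10, "FS": 50.1, "MQ": 50}, ["FS"]),
        ({"QD": 10, "FS": 10, "MQ": 39.9}, ["MQ"]),
        ({"QD": 3.0, "FS": 60.0, "MQ": 30.0}, ["QD", "FS", "MQ"]),
        ({"FS": 10}, []),  # missing annotations: rules not applied
        ({}, []),
    ])
    def test_site_rules(self, ann, expected_flags):
        rec = snp(site_annotations=ann)
        flt.apply_hard_filters([rec], flt.FilterConfig())
        assert rec.filter_flags == expected_flags
        assert rec.passes_filters == (not expected_flags)

    def test_boundary_values_pass(self):
        # thresholds are strict inequalities: QD < 4.0, FS > 50.0, MQ < 40.0
        rec = snp(site_annotations={"QD": 4.0, "FS": 50.0, "MQ": 40.0})
        flt.apply_hard_filters([rec], flt.FilterConfig())
        assert rec.passes_filters

    def test_low_gq_masks_exactly_that_genotype(self):
        rec = snp(genotypes=np.array([0, 1, 2, 1, 0], dtype=np.int8),
                  per_sample_gq=np.array([99, 19, 20, 45, 99]))
        flt.apply_hard_filters([rec], flt.FilterConfig())
        assert rec.genotypes.tolist() == [0, MISSING, 2, 1, 0]

    def test_records_never_deleted(self):
        recs = [snp(site_annotations={"QD": 1.0}), snp(pos=200)]
        out = flt.apply_hard_filters(recs, flt.FilterConfig())
        assert len(out) == 2


class TestSnpClusters:
    def test_three_snps_within_window_all_flagged(self):
        # span 110 - 100 + 1 = 11 <= 15
        flags = flt.flag_snp_clusters([100, 105, 110], flt.FilterConfig())
        assert flags.tolist() == [True, True, True]

    def test_two_snps_not_a_cluster(self):
        flags = flt.flag_snp_clusters([100, 200], flt.FilterConfig())
        assert not flags.any()

    def test_span_sixteen_is_not_flagged(self):
        # 100..115 spans 16 bp inclusive: just outside the 15-bp window
        flags = flt.flag_snp_clusters([100, 107, 115], flt.FilterConfig())
        assert not flags.any()
        assert flt.flag_snp_clusters([100, 107, 114], flt.FilterConfig()).all()

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            flt.flag_snp_clusters([100, 90], flt.FilterConfig())

    def test_matches_brute_force_oracle_on_random_sets(self, rng):
        cfg = flt.FilterConfig()
        for _ in range(20):
            pos = np.sort(rng.choice(np.arange(1, 2000), size=200, replace=False))
            got = flt.flag_snp_clusters(pos, cfg)
            np.testing.assert_array_equal(got, cluster_oracle(pos))


class TestSubstitutions:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("G", "A", "transition"), ("A", "G", "transition"),
        ("C", "T", "transition"), ("T", "C", "transition"),
        ("A", "T", "transversion"), ("A", "C", "transversion"),
        ("G", "T", "transversion"), ("G", "C", "transversion"),
    ])
    def test_classification(self, ref, alt, expected):
        assert flt.classify_substitution(ref, alt) == expected

    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    @settings(deadline=None)
    def test_symmetry(self, x, y):
        if x != y:
            assert flt.classify_substitution(x, y) == flt.classify_substitution(y, x)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            flt.classify_substitution("N", "A")

    def test_ts_tv_ratio_on_toy_set(self):
        refs, alts = zip(("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))
        assert flt.ts_tv_ratio(refs, alts) == 1.0


class TestGenotypeSummary:
    def test_hom_het_counting(self):
        m = make_matrix(np.array([[0], [1], [2], [MISSING]], dtype=np.int8))
        out = flt.summarize_genotypes(m)
        assert out.loc[0, "het"] == 1
        assert out.loc[0, "hom_alt"] == 1

    def test_all_missing_sample(self):
        m = make_matrix(np.full((5, 1), MISSING, dtype=np.int8))
        out = flt.summarize_genotypes(m)
        assert out.loc[0, ["het", "hom_alt"]].tolist() == [0, 0]

    def test_matches_direct_tally(self, rng):
        dosage = rng.integers(-1, 3, size=(500, 6)).astype(np.int8)
        out = flt.summarize_genotypes(make_matrix(dosage))
        for j in range(6):
            assert out.loc[j, "het"] == int((dosage[:, j] == 1).sum())
            assert out.loc[j, "hom_alt"] == int((dosage[:, j] == 2).sum())


class TestNovelty:
    def test_exact_key_match_is_known(self):
        known = {("chr1", 100, "A", "G")}
        assert flt.classify_novelty([snp(100)], known) == ["known"]

    def test_allele_mismatch_at_known_position_is_novel(self):
        known = {("chr1", 100, "A", "C")}
        assert flt.classify_novelty([snp(100)], known) == ["novel"]

    def test_empty_known_set(self):
        assert flt.classify_novelty([snp(), snp(200)], set()) == ["novel", "novel"]


@pytest.fixture
def gene_models():
    return [
        GeneModel("g1", "g1", "chr1", 1000, 2000, "+",
                  exons=[(1000, 1200), (1800, 2000)]),
        GeneModel("g2", "g2", "chr1", 5000, 6000, "-", exons=[(5000, 6000)]),
    ]


class TestRegions:
    def test_exonic_intronic_intergenic(self, gene_models):
        recs = [snp(1100), snp(1500), snp(3000)]
        assert flt.classify_region(recs, gene_models) == \
            ["exonic", "intronic", "intergenic"]

    def test_partition_and_oracle_on_random_positions(self, rng, gene_models):
        positions = rng.integers(1, 10_000, size=1000)
        recs = [snp(int(p)) for p in positions]
        got = flt.classify_region(recs, gene_models)

        def oracle(pos):
            p = pos - 1
            for g in gene_models:
                for s, e in g.exons:
                    if s <= p < e:
                        return "exonic"
            for g in gene_models:
                if g.start <= p < g.end:
                    return "intronic"
            return "intergenic"

        assert got == [oracle(int(p)) for p in positions]
        counts = {c: got.count(c) for c in set(got)}
        assert sum(counts.values()) == len(recs)


class TestIndelClasses:
    def indel(self, pos, delta):
        cls = "insertion" if delta > 0 else "deletion"
        ref = "A" * (1 + max(-delta, 0))
        alt = "A" * (1 + max(delta, 0))
        return VariantRecord(chrom="chr1", pos=pos, ref_allele=ref,
                             alt_allele=alt, variant_class=cls,
                             length_change=delta)

    def test_exonic_in_frame_deletion(self, gene_models):
        assert flt.classify_indel(self.indel(1100, -3), gene_models) == \
            "non-frameshift deletion"

    def test_exonic_frameshift_insertion(self, gene_models):
        assert flt.classify_indel(self.indel(1100, 2), gene_models) == \
            "frameshift insertion"

    def test_non_exonic_labelled_by_region(self, gene_models):
        assert flt.classify_indel(self.indel(1500, 2), gene_models) == \
            "intronic insertion"
        assert flt.classify_indel(self.indel(3000, -1), gene_models) == \
            "intergenic deletion"

    def test_over_50bp_rejected(self, gene_models):
        with pytest.raises(ValueError, match="51"):
            flt.classify_indel(self.indel(1100, -51), gene_models)
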