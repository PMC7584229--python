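import numpy as np
import pandas as pd
import pytest

from sweepscan import sweep
from sweepscan.model import GeneModel


def stats_frame(fst, ratio, chrom=None, start=None, eligible=None):
    n = len(fst)
    start = start if start is not None else np.arange(n) * 10_000
    df = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * n,
        "start": start,
        "end": np.asarray(start) + 100_000,
        "fst": fst,
        "pi_ratio": ratio,
        "eligible": eligible if eligible is not None else [True] * n,
    })
    return df


class TestPiRatio:
    def test_reference_over_test_orientation(self):
        assert sweep.pi_ratio(0.003, 0.001) == pytest.approx(3.0)

    def test_identity(self):
        assert sweep.pi_ratio(0.002, 0.002) == pytest.approx(1.0)

    def test_zero_test_diversity_is_infinite(self):
        assert np.isposinf(sweep.pi_ratio(0.002, 0.0))
        assert np.isnan(sweep.pi_ratio(0.0, 0.0))

    def test_elementwise_division(self, rng):
        a = rng.uniform(0.001, 0.01, 50)
        b = rng.uniform(0.001, 0.01, 50)
        np.testing.assert_allclose(sweep.pi_ratio(a, b), a / b, rtol=1e-15)


class TestEmpiricalThreshold:
    def test_nearest_rank_on_1_to_100(self):
        values = np.arange(1, 101, dtype=float)
        t = sweep.empirical_threshold(values, q=0.95)
        assert t == 95.0
        assert sorted(v for v in values if v >= t) == [95, 96, 97, 98, 99, 100]

    def test_all_equal_selects_everything(self):
        values = np.full(50, 7.0)
        t = sweep.empirical_threshold(values)
        assert t == 7.0 and (values >= t).all()

    def test_selected_fraction_on_random_floats(self):
        rng = np.random.default_rng(3)
        v = rng.random(1000)
        t = sweep.empirical_threshold(v, q=0.95)
        frac = (v >= t).mean()
        assert 0.04 <= frac <= 0.06

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError, match="20"):
            sweep.empirical_threshold(np.arange(10.0))

    def test_infinite_values_ignored(self):
        v = np.concatenate([np.arange(1.0, 101.0), [np.inf] * 10])
        assert sweep.empirical_threshold(v, 0.95) == 95.0


class TestOutlierSelection:
    def test_joint_condition(self):
        df = stats_frame(fst=[0.5, 0.5, 0.01, 0.5],
                         ratio=[3.0, 0.5, 3.0, np.inf])
        sel = sweep.select_outlier_windows(df, t_fst=0.05, t_ratio=1.07)
        assert sel.tolist() == [True, False, False, True]

    def test_inclusive_at_threshold(self):
        df = stats_frame(fst=[0.05], ratio=[1.07])
        assert sweep.select_outlier_windows(df, 0.05, 1.07).all()

    def test_ineligible_windows_never_selected(self):
        df = stats_frame(fst=[0.9], ratio=[9.0], eligible=[False])
        assert not sweep.select_outlier_windows(df, 0.05, 1.07).any()

    def test_matches_brute_force_conjunction(self, rng):
        df = stats_frame(fst=rng.random(200), ratio=rng.uniform(0, 4, 200))
        sel = sweep.select_outlier_windows(df, 0.6, 2.0)
        brute = [(f >= 0.6) and (r >= 2.0)
                 for f, r in zip(df["fst"], df["pi_ratio"])]
        assert sel.tolist() == brute

    def test_raising_q_never_enlarges_outlier_set(self, rng):
        df = stats_frame(fst=rng.random(100), ratio=rng.uniform(0.5, 3, 100))
        sizes = []
        for q in (0.80, 0.90, 0.95, 0.99):
            t_f = sweep.empirical_threshold(df["fst"], q)
            t_r = sweep.empirical_threshold(df["pi_ratio"], q)
            sizes.append(int(sweep.select_outlier_windows(df, t_f, t_r).sum()))
        assert sizes == sorted(sizes, reverse=True)


class TestLocusMerging:
    def test_overlapping_windows_merge(self):
        df = stats_frame(fst=[0.5, 0.6], ratio=[2.0, 3.0], start=[0, 10_000])
        loci = sweep.merge_windows_to_loci(df)
        assert len(loci) == 1
        locus = loci[0]
        assert (locus.start, locus.end) == (0, 110_000)
        assert locus.n_windows == 2
        assert locus.max_fst == 0.6 and locus.max_pi_ratio == 3.0

    def test_different_chromosomes_never_merge(self):
        df = stats_frame(fst=[0.5, 0.5], ratio=[2, 2], chrom=["chr1", "chr2"],
                         start=[0, 0])
        assert len(sweep.merge_windows_to_loci(df)) == 2

    def test_abutting_windows_merge(self):
        df = stats_frame(fst=[0.5, 0.5], ratio=[2, 2], start=[0, 100_000])
        assert len(sweep.merge_windows_to_loci(df)) == 1

    def test_matches_interval_union_oracle_and_idempotent(self, rng):
        starts = rng.choice(np.arange(0, 3_000_000, 10_000), size=50,
                            replace=False)
        df = stats_frame(fst=rng.random(50), ratio=rng.uniform(1, 5, 50),
                         start=np.sort(starts))
        loci = sweep.merge_windows_to_loci(df)
        # interval-union oracle
        intervals = sorted((s, s + 100_000) for s in starts)
        merged = []
        for s, e in intervals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        assert [(l.start, l.end) for l in loci] == [tuple(m) for m in merged]
        # covered bases conserved
        union_len = sum(e - s for s, e in merged)
        assert sum(l.end - l.start for l in loci) == union_len
        # idempotent: merging the loci again changes nothing
        df2 = stats_frame(fst=[l.max_fst for l in loci],
                          ratio=[l.max_pi_ratio for l in loci],
                          start=[l.start for l in loci])
        df2["end"] = [l.end for l in loci]
        again = sweep.merge_windows_to_loci(df2)
        assert [(l.start, l.end) for l in again] == [(l.start, l.end) for l in loci]


class TestGeneAssignment:
    genes = [GeneModel("gA", "gA", "chr1", 50_000, 60_000, "+"),
             GeneModel("gB", "gB", "chr1", 109_999, 120_000, "+"),
             GeneModel("gC", "gC", "chr1", 500_000, 510_000, "+"),
             GeneModel("gD", "gD", "chr2", 50_000, 60_000, "+")]

    def test_overlap_rules(self):
        from sweepscan.model import SweepLocus

        locus = SweepLocus("chr1", 0, 110_000, 1, 0.5, 2.0)
        sweep.assign_genes([locus], self.genes)
        # gA inside; gB overlaps by exactly 1 bp; gC beyond; gD other chrom
        assert locus.genes == ["gA", "gB"]

    def test_no_overlap_unassigned(self):
        from sweepscan.model import SweepLocus

        locus = SweepLocus("chr1", 200_000, 300_000, 1, 0.5, 2.0)
        sweep.assign_genes([locus], self.genes)
        assert locus.genes == []


class TestSharedLoci:
    def _result(self, outlier_mask, rng):
        n = len(outlier_mask)
        df = stats_frame(fst=rng.random(n), ratio=rng.uniform(1, 3, n))
        df["outlier"] = outlier_mask
        df["comparison"] = "x"
        return sweep.ComparisonResult("x", df, 0.1, 1.1)

    def test_identical_sets_shared_fully(self, rng):
        mask = rng.random(40) < 0.3
        results = [self._result(mask, rng) for _ in range(3)]
        shared_w, loci, _ = sweep.shared_loci(results)
        assert len(shared_w) == mask.sum()

    def test_disjoint_sets_share_nothing(self, rng):
        m1 = np.zeros(40, bool); m1[:5] = True
        m2 = np.zeros(40, bool); m2[20:25] = True
        shared_w, loci, genes = sweep.shared_loci(
            [self._result(m1, rng), self._result(m2, rng)])
        assert len(shared_w) == 0 and loci == [] and genes == []

    def test_matches_brute_force_triple_intersection(self, rng):
        masks = [rng.random(60) < 0.4 for _ in range(3)]
        results = [self._result(m, rng) for m in masks]
        shared_w, _, _ = sweep.shared_loci(results)
        expected = np.logical_and.reduce(masks)
        assert len(shared_w) == expected.sum()
        assert shared_w["start"].tolist() == \
            results[0].stats.loc[expected, "start"].tolist()

    def test_mismatched_grids_rejected(self, rng):
        r1 = self._result(np.zeros(30, bool), rng)
        r2 = self._result(np.zeros(31, bool), rng)
        with pytest.raises(ValueError, match="grid"):
            sweep.shared_loci([r1, r2])

    def test_venn_counts_partition_outliers(self, rng):
        masks = [rng.random(50) < 0.4 for _ in range(3)]
        results = [self._result(m, rng) for m in masks]
        results[1].comparison = "y"
        results[2].comparison = "z"
        venn = sweep.venn_counts(results)
        assert venn["n_windows"].sum() == int(np.logical_or.reduce(masks).sum())
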