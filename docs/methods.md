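# Methods

## Scope and data model

The pipeline operates on biallelic SNPs. A VCF is read into a sites ×
samples alt-allele dosage matrix (0/1/2, with a missing mask); InDels
(retained only up to 50 bp of length change) and multiallelic sites are
kept as flagged records for the summary tables but never enter the
window statistics: the diversity and differentiation estimators below
are defined on allele frequencies at biallelic sites, and no published
decomposition rule exists for this scan, so multiallelic SNPs are
excluded rather than decomposed. All internal intervals are 0-based
half-open; VCF positions are 1-based at the boundary and BED output is
0-based half-open, with exactly one conversion layer in the I/O module.
Chromosomes keep the order of the VCF header; no natural-sort is
assumed.

Groups are defined by a `sample → breed → group` map. Group-level SNP
sets are unions over breeds (`merge_group_snps`): a sample lacking a
call at a union site is missing there, and conflicting ref/alt alleles
at one position are an error rather than silently resolved.

## Hard filters

Site filters follow GATK VariantFiltration semantics — a rule applies
only where its annotation exists: fail if QD < 4.0, FS > 50.0 or
MQ < 40.0; genotypes with GQ < 20 are set missing. The SNP-cluster rule
flags every SNP lying in any inclusive 15-bp span containing ≥ 3 SNPs
(the window is an inclusive base-pair span, pos_j − pos_i + 1 ≤ 15; this
is GATK's convention and is verified against a brute-force all-windows
scan). Whether cluster-flagged SNPs are dropped before the window
statistics or only annotated is configurable (`drop_clustered`, default
true), since either reading of the upstream protocol is defensible.

## Diversity, F_ST and windows

Per-site diversity is the unbiased mean pairwise difference over the n
called allele copies, π_site = n/(n−1)·2p(1−p); phase is never required
because the estimator (and its brute-force test oracle) enumerate
unphased allele copies, not haplotypes. Window π sums π_site over the
window and divides by the **window span in bp** (the convention of the
standard windowing tools); dividing by SNP count instead is available as
`pi_denominator: n_sites`. Windows are 100 kb sliding in 10-kb steps;
starts run 0, step, 2·step, … while start < L, so a 250-kb chromosome
has 16 full windows and truncated tails, which are retained but flagged
(dropping them would silently lose terminal genes); their π uses the
actual span.

F_ST defaults to the Weir & Cockerham (1984) two-population variance
components a, b, c computed per site from diploid sample sizes, allele
frequencies and observed heterozygote proportions, aggregated per window
as Σa / Σ(a+b+c) and clamped at 0 (negative estimates are sampling
noise; thresholds are defined on [0, 1]). A site contributes only when
both populations have ≥ 2 called allele copies and more than one diploid
overall. A Hudson-style ratio-of-sums estimator is provided as a
configuration alternative for sensitivity analysis.

Windows with fewer than `min_sites` (default 10) usable sites are
excluded from quantile computation and outlier calling: the π-ratio of a
near-empty window is numerically unstable and would dominate the tails.

## Outlier calling and loci

The π-ratio is oriented reference/test, so high values mean diversity
loss in the test population. Thresholds are empirical nearest-rank upper
quantiles (value at rank ⌈q·n⌉ of the ascending sort, default q = 0.95)
with inclusive ≥ selection, computed per comparison on the eligible
windows; at least 20 finite values are required or the scan aborts with
advice to enlarge the input. A window is a candidate iff it passes both
thresholds *in the same window* (the alternative — intersecting two
separately merged region sets — is available by flag but not default).
Windows where π_test = 0 have an undefined (infinite) ratio: they are
excluded from the quantile computation but do qualify as outliers when
their F_ST passes, because zero test diversity over nonzero reference
diversity is the extreme form of the scanned signal. Candidate windows
overlapping or abutting on a chromosome merge into loci whose statistics
are maxima over members; both window counts and locus counts are
reported, since the field's literature uses the two interchangeably.
Genes attach to a locus by ≥ 1 bp gene-body overlap (a promoter flank is
a config knob, default 0). Shared loci across comparisons are computed
on the identical window grid as the intersection of outlier-window sets,
then merged and gene-annotated the same way.

## CNV regions

Per-individual CNV calls overlapping by ≥ 1 bp on a chromosome merge
transitively into a CNVR regardless of sample and type (a deletion and a
duplication merge into one CNVR listing both types; type-stratified
merging is a config option). Abutting calls do not merge. Length classes
are < 10 kb (strict), 10–100 kb (boundaries inclusive) and > 100 kb
(strict); sharing classes are 1 / 2 / ≥ 3 contributing individuals.

## Enrichment

One-sided over-representation p = P(X ≥ k) under
Hypergeometric(N, K, n), BH step-up q-values, strict significance
Q < 0.05. Term mappings come from a user-supplied two-column file rather
than a live GO/KEGG download, for reproducibility offline. Candidate
genes annotated to no term remain in n — they inform the null. A
uniform-null simulation (200 p-values, 1,000 replicates) keeps the
any-discovery rate at the 5% level below 7%.

## The simulator

`simulate_populations` draws, per site, an ancestral frequency
p₀ ~ Uniform(0.05, 0.95) and per population a Balding–Nichols frequency
Beta(p₀(1−F)/F, (1−p₀)(1−F)/F); genotypes are Binomial(2, p_pop) per
diploid and missingness is uniform. Balding–Nichols was chosen over a
coalescent simulator because it gives direct, analytic control of the
differentiation level (E[F_ST] ≈ F) with exact per-site truth; a
coalescent cross-check is a possible extension. Sweeps are implanted at
the frequency level, not through selection dynamics — the test
population's frequency inside each sweep interval is pushed toward the
nearer of {0, 1} by factor `s_fst` and collapsed to monomorphic with
probability `s_pi` — because the benchmark needs exact ground truth, not
mechanistic realism.

Defaults mirror the study design the pipeline serves: one test breed of
12 diploids versus reference groups of 4/3/3 breeds × 10 diploids;
F = 0.10 (window F_ST then calibrates into 0.05–0.15); ~1 SNP per
500 bp (mid-range for a livestock resequencing call set after
filtering); three 10-Mb chromosomes with one 500-kb sweep each at
s_pi = s_fst = 0.9; missing rate 2%. Within-group breed-level
differentiation (`breed_f`) defaults to 0 so that a two-population run
calibrates exactly at F; it can be raised to emulate breed structure.
Gene models are tiled non-overlapping (5–30 kb genes, 2–6 exons,
10–60 kb gaps); the term map contains one sweep-linked term (genes
inside sweep intervals) plus 20 random background terms. CNVR truth
intervals are placed disjoint with margins larger than the call jitter,
so jitter can shrink but never bridge regions; the
deletion:duplication ratio defaults to 3:1. All randomness flows from a
single seed through fixed-offset substreams, so identical configs give
byte-identical fixtures.

What the simulator does *not* emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium and recombination
structure (sites are independent), mutation-rate heterogeneity and
ascertainment of the call set, genotyping error beyond uniform
missingness, admixture or uneven relatedness within breeds, and sweeps
with soft or partial signatures. Recovery rates on the benchmark are
upper bounds for field performance.

## Numerical and reporting choices

Degenerate inputs are handled explicitly: sites with no called copies
are skipped per population; windows with zero usable sites report π = 0,
undefined F_ST and are ineligible; empty window sets raise rather than
return empty quantiles. The per-window TSVs print 6 significant figures;
the manifest stores thresholds at 10 decimals and contains no
timestamps, so a rerun with the same config and seed reproduces it
byte-for-byte (the manifest digest is the determinism check). Problem
sizes in the test-suite benchmark (a ~60k-site, 112-sample genome; 5k-site
calibration runs) were chosen as the smallest sizes at which the
empirical quantiles and calibration bands are stable.

## Known limitations

Only two-population F_ST is implemented (the scan is pairwise by
design); no haplotype statistics (iHS, XP-EHH) or composite-likelihood
methods; no GO graph propagation in enrichment; CNVR merging has no
reciprocal-overlap option; the VCF reader loads genotypes into memory,
which is fine for the multi-Mb scale it targets but not for whole
mammalian genomes at full density.
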