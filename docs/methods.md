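# Methods

This note documents the statistical machinery in `methylinta`, the
assumptions behind it, and the choices made where the design was
genuinely open.

## Setting

The package targets a common comparative-epigenomics design: several
tissues or conditions (nine by default), each profiled once by
whole-genome bisulfite sequencing (WGBS) and once by RNA-seq, with no
biological replicates. Analysis proceeds through every unordered
sample pair (36 comparisons for nine samples). Methylation is read
per cytosine as (methylated reads, total reads) in the three plant
sequence contexts — CG, CHG and CHH (H = A, T or C), determined by
the two bases downstream of the cytosine on its own strand — and
stratified by gene feature: 5 kb upstream flank, 5'UTR, exon, intron,
3'UTR, 5 kb downstream flank, or intergenic.

## Differential methylation

### Site filtering

Only sites covered by at least 7 reads in **every** sample are
tested. The threshold is the conventional minimum for a usable
per-site proportion estimate in pairwise WGBS comparisons;
`min_reads` is configurable.

### The smoothed Wald test

Without replicates, neighboring cytosines of the same context act as
pseudo-replicates. For a site *s* and sample *x*, the smoothed level
pools counts over the window *W(s)* of same-chromosome, same-context
sites within ±250 bp (window 500 bp, configurable):

    p̂_x(s) = Σ_{i∈W} m_i / Σ_{i∈W} n_i

The test statistic for a comparison (A, B) is the Wald ratio

    z = (p̂_A − p̂_B) / sqrt(var_A + var_B),
    var_x = p̂(1−p̂) · (1 + (ñ−1)·φ̂) / Ñ

with Ñ the pooled window coverage, ñ the mean per-site coverage in
the window, and φ̂ a local beta-binomial dispersion. Two-sided
p-values come from the standard normal. If both variances vanish
(window levels exactly 0 or 1), p = 1 when the difference is 0 and
the smallest positive float otherwise.

**Dispersion estimation.** φ̂ is a method-of-moments estimate from
the spread of per-site proportions in the window. Crucially, the
spread is measured by **first differences of neighboring
proportions**, E[(p_{i+1} − p_i)²/2] = var(p) for independent noise,
rather than by the raw window variance: raw variance also absorbs
genuine mean structure (UTR depletion, DMR edges), which would
inflate φ̂, miscalibrate the null, and mask short DMRs. The moment
equation var(p) = p(1−p)(φ + (1−φ)·mean(1/n_i)) is solved for φ and
clipped to [1e−3, 0.5] (floor exercised by single-site windows, cap a
guard against degenerate estimates). Measured on a simulated null
methylome (identical beta-binomial parameters in both samples, 10,000
CG sites at 30×), the rejection rate at α = 0.05 is 0.050–0.052.

### DMC and DMR calling

A DMC is a tested site with p < α (0.05). Two modes share one code
path and differ only in the effect-size filter:

* **gene-model mode** (default): no additional filter
  (`min_abs_diff = 0`);
* **whole-genome mode**: additionally |p̂_A − p̂_B| > 0.25.

DMRs chain consecutive same-direction DMCs (per chromosome, context
and comparison) with inter-DMC gaps ≤ 100 bp; a maximal chain with
≥ 3 members spanning ≥ 50 bp is a DMR bounded by its outermost member
positions, with `mean_diff` the mean of member differences. The gap
rule (the region-membership criterion leaves it open) is 100 bp,
configurable; direction homogeneity is required because hypo/hyper
DMRs are tallied separately downstream.

**A caveat that shapes two choices.** Testing a *window mean* at
*site* resolution makes neighboring p-values strongly correlated:
under the null, the 5% of false positives arrive in runs that can
satisfy the 3-DMC/50-bp rule, and around a true DMR a "halo" of
significant sites extends up to half a window beyond the real edge.
Consequently (i) genome-scale DMR scans should run in whole-genome
mode — the >25% filter removes the small-difference false chains —
and (ii) the smoothing window should not exceed the scale of the
regions sought, since a 500 bp window dilutes a 200 bp region's
difference of 0.4 down to ≈ 0.16, below the 0.25 filter. The planted
recovery analysis (200 CG DMRs, Δ = 0.4, 200 bp wide, ≥ 10 sites,
30×) therefore uses whole-genome mode with a 200 bp window and
achieves sensitivity 1.0 with ≥ 99% of called span inside planted
spans and no false DMRs. Gene-model mode keeps the defaults; its
p-only DMC definition is deliberately permissive (every covered gene
accumulates some calls), which is appropriate when DMC counts serve
as gene-level evidence rather than as a genome-wide catalogue.

Raw p-values are not multiplicity-corrected by default (an optional
Benjamini–Hochberg mode exists); the downstream consumers treat DMC
sets as evidence tallies per gene, not as inference-grade lists.

## Differential expression

One library per condition means no dispersion estimation: the
negative-binomial dispersion is fixed at φ = BCV², with a biological
coefficient of variation of 0.2 — the conventional value for this
design in plants.

Counts are scaled to a common effective library size. The default
normalization is TMM (trimmed mean of M-values: reference = sample
whose upper quartile is closest to the mean upper quartile, trim 30%
on M and 5% on A, precision weights from the delta-method variance of
M, factors normalized to unit geometric mean); `upper-quartile` and
`none` are available. Pseudo-counts at the common size are obtained
by linear scaling and rounding — with single libraries the
quantile-matching refinement is immaterial, and correctness of the
test itself is pinned by an enumeration oracle.

The exact conditional test: given total t = y'_A + y'_B, each side is
NB(mean t/2, dispersion φ) and the p-value sums the probabilities of
all splits (a, t−a) no more likely than the observed one, normalized
over all t+1 splits (relative tolerance 1e−10 for floating-point
ties). t = 0 gives p = 1. log2 fold changes use a 0.5 prior count so
zero counts give finite, sign-correct values. Agreement with naive
enumeration is < 2e−14 over every split of every total t ≤ 200;
measured null rejection (5,000 NB genes, mean 100) is 0.047, and
power is monotone in the true fold change.

Genes with zero counts in both samples are reported untested. A DEG
is a tested gene with p < 0.05.

## Integration

For each comparison, every gene seen in any input is classified:
**DEM** (differentially expressed with ≥ 1 DMC or DMR), **DEG-only**,
**DM-only** (methylation evidence, not DE), or **neither**. DMCs are
assigned to genes by position; DMRs by their midpoint (a single label
keeps count matrices well-defined for straddling regions). Where a
position falls in features of two genes, the nearer TSS wins, then
the lexicographically smaller gene id; within a gene UTR > exon >
intron > flank (UTRs are parts of exons in GFF3 but are tallied as
their own stratum).

Gene-level methylation difference is the unweighted mean of the
gene's DMR mean differences (body plus flanks); opposite-sign DMRs
may cancel — this is intentional, matching the idea of a net
methylation shift per locus.

**Correlations.** Within each context × feature stratum, the Pearson
correlation is computed between a gene-comparison's expression logFC
and its mean methylation difference in that stratum, with a
t-distributed two-sided p-value. Cells with < 3 points or zero
variance are reported as undefined together with their n; p-values
are per-cell, unadjusted (a Bonferroni option exists). Missing
methylation differences are *excluded* from correlations but imputed
as 0 for clustering — correlations must not be diluted by imputed
zeros, while clustering needs a complete matrix.

**Clustering.** DEM methylation-difference profiles (genes ×
comparisons) are clustered by Ward linkage on Euclidean distances
(correlation distance optional) and cut with the simple "tree"
variant of the dynamic tree cut: recursively split at the highest
merges, accept a branch as a cluster iff it has ≥ 30 leaves, and fold
smaller leftover branches into the accepted cluster with the nearest
centroid. Labels K1, K2, … are ordered by descending size with ties
broken by smallest member id, so the partition and its labels are
invariant to row order.

**Quadrants.** Per focal sample, each DEM event is labeled by the
signs of its (methylation difference, logFC) after re-orienting the
comparison so the focal sample comes first: M−E−, M−E+, M+E−, M+E+.
Zero differences are excluded and tallied. Reversing a comparison
permutes M−E+ ↔ M+E− and M−E− ↔ M+E+.

**PCA.** The comparisons × (context × feature) DMC/DMR count matrix
is column-standardized (zero-variance columns dropped with a warning)
and decomposed by SVD; component signs are fixed by making the
largest-magnitude loading positive.

## Enrichment and networks

Term enrichment is a one-sided (over-representation) hypergeometric
test per flat term label, Bonferroni-corrected over the terms tested
(K > 0 in the universe). The default universe is the analysis count
matrix's gene set. Agreement with exact integer combinatorics is at
machine precision for all universe sizes ≤ 50.

The co-expression network uses Spearman's rho (average ranks on
ties) across samples on log2(CPM+1) expression; an edge requires
rho **strictly** above 0.95. On nine samples this demands near-perfect
monotone agreement — rho = 0.95 exactly (three adjacent rank swaps)
is excluded by design. Genes without an edge are dropped from the
graph but listed in a sidecar. Communities come from
Clauset–Newman–Moore greedy modularity agglomeration on the
unweighted thresholded graph (weights would contradict the
binarization), with ΔQ ties broken by the smallest lexicographic node
pair so results do not depend on Python's randomized string hashing;
the partition with the highest modularity encountered is returned.
Retained communities can be filtered to those containing at least
one flagged gene (a pathway list of interest) and are renumbered by
descending size.

## The synthetic-data generator

`synthetic_data` emulates the study design so every stage is testable
without downloads. Defaults: 9 samples (named after the study's
organs/conditions), coverage ~ truncated-Poisson(30), context means
CG 0.70 > CHG 0.45 > CHH 0.08, UTR depletion factor 0.3 (both UTRs),
site-level beta dispersion 0.01 (beta-binomial rather than binomial
counts, so the dispersion machinery of the Wald test is exercised),
NB expression at BCV 0.2 with lognormal(4, 1) gene means and mild
lognormal(0, 0.1) library-size variation. Genes (2–6 exons, UTRs at
both ends) are placed with ≥ 12 kb spacing so 5 kb flanks never
overlap. Planted DMRs shift the context mean by ±δ (clipped to
[0.02, 0.98]) over a contiguous window in chosen samples; placement
requires enough target-context sites and retries up to 100× before
erroring, so planted truths are never vacuously unrecoverable.
Planted DEM blocks couple a methylation shift in a chosen feature
with an expression log-fold-change of configurable sign (negative
coupling: hypermethylated ⇒ repressed), optionally with a shared
per-sample expression profile (`coexpression_sdlog`) that makes a
block behave like a co-regulated pathway across tissues — without it,
rho > 0.95 edges are rare on nine samples. Every output is a
deterministic, byte-identical function of the seed; truth tables
record all planted structure.

What the generator does **not** emulate: linkage between methylation
and sequence composition, transposable elements and repeats,
conversion errors, mapping bias, strand-asymmetric coverage, batch
structure, or biological replicate variance. Passing recovery tests
therefore demonstrates the pipeline's statistical behavior under its
own model assumptions, not performance on real libraries.

## Problem sizes in the validation runs

The calibration and recovery analyses use sizes chosen to give
stable estimates at desk scale: 10,000 sites for null calibration,
200 planted DMRs for recovery, all totals ≤ 200 for exact-test
enumeration, and a 160-gene / 4-sample / 2 × 1.3 Mb run with two
50-gene DEM blocks (affected in different samples, so both
comparison orientations occur) for the end-to-end coupling analysis
— the measured gene-body CG correlation there is ≈ −0.85 between
methylation difference and logFC. The demonstration analysis under
`analysis/` uses nine samples on a smaller genome, plants regions
wider (700 bp) than the smoothing window so their differences
survive smoothing at full strength, and applies the >25% filter in
its genome-wide DMC scan for the reasons above.

## Known limitations

* Site-level p-values inherit the window correlation of smoothing;
  they are evidence scores, not independent tests, and the package
  deliberately reports raw p-values by default.
* The dispersion moment estimator can hit its floor in sparse
  windows, making isolated-site tests anti-conservative when counts
  are truly overdispersed; coverage filtering mitigates this.
* With one library per condition the exact test's fixed BCV is an
  assumption, not an estimate; results shift with `--bcv`.
* The dynamic tree cut implements the simple "tree" variant only;
  the hybrid variant (which needs per-object distances to cluster
  cores) is out of scope.
* GO terms are flat labels; no DAG propagation is performed.
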