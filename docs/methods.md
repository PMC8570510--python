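# Methods

This note documents the statistical models, numerical choices and design
decisions behind `ctxatac`, and what the synthetic-data tests do and do not
establish.

## Coordinates and interval algebra

All coordinates are 0-based half-open internally (BED convention); 1-based
positions (GWAS catalog, VCF-style variant tables) are converted at ingest
and back at export. Overlap means >= 1 shared base under half-open
semantics, so `[200,300)` and `[300,400)` do not overlap while `[200,300)`
and `[299,400)` share exactly one base. Merging treats book-ended intervals
(end == next start) as mergeable, matching the default of the standard
merge tool. Strand is carried as metadata and ignored by every overlap
rule. These conventions are load-bearing: every downstream rule (consensus
support, Hi-C/eQTL/GWAS overlap, AI variant-in-peak assignment) reduces to
this one primitive, which is verified against per-base boolean-array and
quadratic-scan oracles.

## Library QC

TSS enrichment is computed on 2,001-bp windows centred on TSSs: coverage is
summed across windows per position and the centre value (index 1000) is
divided by the mean over the flank positions. The phrase "the 100 bases at
the leftmost and rightmost ends" is read as 100 positions at EACH end (200
background positions total); the alternative reading (100 total, 50 per
end) is available via `flank_mode="total"`. The statistic is invariant to
scaling the coverage and undefined (error) when all flank positions are
zero. Pass rules are applied exactly as stated per cohort: cultured-cell
libraries need FRiP > 0.20 and TSS enrichment > 5 (both strict); tissue
libraries need TSS enrichment >= 4 (weak).

The outlier screen normalises counts per sample depth, takes log2(x+1),
centres features, projects samples onto the top 10 principal components and
clusters them with complete-linkage hierarchical clustering on Euclidean
distances. The linkage and the cut height are not prescribed by the method
being reproduced (only a dendrogram cutoff line is shown), so the cut
height is a user parameter; every sample outside the largest cluster at the
cut is flagged.

## Consensus peaks

Per day, the union of replicate peaks is merged and a merged region is kept
when strictly more than half of the replicates contribute an overlapping
peak (3/5, 6/10). For ranking, each replicate contributes the smallest
p-value among its peaks overlapping the region - the best-peak-per-replicate
reading; pooling all overlapping peak p-values instead is available behind
a flag - and replicates with no overlapping peak contribute p = 1, which
penalises low-reproducibility regions. The median is taken over all
replicates, peaks are sorted ascending with (chrom, start) tie-breaks, the
top K (default 100,000) per day are kept, and the per-day top sets are
merged into the cross-day test set.

## Differential testing

**Size factors** are median-of-ratios over features positive in every
sample, rescaled to geometric mean 1 (the rescaling changes nothing
downstream since only ratios enter the offsets, but makes factors
comparable across runs). Data with no all-positive feature raise an error
suggesting a pseudo-reference fallback rather than silently switching
estimators.

**GC offsets.** Within each sample, features are split into 10 equal-count
GC bins; each bin's count distribution is full-quantile-mapped onto the
mean of the bin-wise quantile functions, evaluated at each feature's exact
within-bin quantile (average ranks for ties). The factor is raw/normalised,
1 for zero counts, and factor rows are rescaled to per-feature geometric
mean 1. This absorbs sample-specific multiplicative GC bias while
preserving within-bin rank order.

**NB GLM.** Each feature is modelled as NB2 (Var = mu + alpha mu^2) with
log mu_ij = log(offset_ij) + beta_0 + beta_1 group_j. Group means are
orthogonal under this parametrisation, so each group's log-mean solves a
one-dimensional score equation, fit by damped Newton iteration (30 steps,
steps clipped to 2, log-means clipped to +-30; the score is strictly
decreasing so convergence is robust). Dispersion is estimated per feature
by profile maximum likelihood on a 24-point log grid over [1e-8, 50] with
an 8-point refinement, with a Cox-Reid adjustment (subtracting half the log
determinant of the expected information of the mean parameters) that
counters the downward bias of plug-in ML dispersions in small designs.
There is no empirical-Bayes shrinkage across features - a deliberate
deviation from the heavier reference implementations; correctness is
established through simulation-based error control rather than numerical
identity with them.

**Wald reference.** The Wald statistic lfc/se (log2 scale; se from the
inverse expected information of the two group means) is referred to a
Student t distribution with n_samples - 2 degrees of freedom rather than a
normal. With 5v5 replicates and plug-in dispersions the normal reference is
anticonservative (empirical type-I 0.08 at nominal 0.05 on the simulated
null); the t reference restores calibration (0.047). The cost is heavier
tails: overwhelming effects bottom out near p ~ 1e-6 rather than 1e-12,
which does not affect any thresholded call.

All-zero features receive NA p-values and are excluded from the BH
denominator. Calls use q < 0.05 AND |LFC| > 1, both strict; background
features need q > 0.5 AND |LFC| < 1 in every comparison, both strict.
Context classes are assigned with precedence preadipocyte > adipocyte >
mature-adipocyte-specific > other, each requiring significance with the
stated directions in the stated pair of comparisons.

## Peak-gene linking

Hi-C pairs are typed bait-bait when the other end covers any bait fragment.
For bait-bait loops a peak on either end links only to the gene(s) on the
opposite end - the loop is read as a promoter-promoter contact and the
regulated gene is the one the peak is not sitting on; linking a peak to the
gene of its own end as well is a defensible alternative the method text
does not support. eQTL proxies require r^2 strictly > 0.8; "inside a peak"
means the 0-based position falls in [start, end). DE evidence is attached
to existing links only. Peak-to-TSS distance is 0 when the TSS is inside
the peak, otherwise the distance from the nearer of the two half-open edge
coordinates - with a peak [100,200) and TSS 500 the distance is 300.

## GWAS clumping and EFO counting

After filtering (single rs-number SNVs, biallelic per the allele table,
p < 5e-8 strict), each variant keeps its best p across traits and variants
are ordered by the key (p, chrom, pos) - the positional tie-break makes
equal-p outcomes deterministic. The removal rule is implemented pairwise,
exactly as stated: a variant is removed iff some strictly-earlier-keyed
variant within 1 Mb (inclusive) has r^2 > 0.8 with it, whether or not that
remover itself survives. For bookkeeping, removed variants are assigned to
the best-keyed surviving remover, following the removal chain when
necessary; this affects only member lists, never the survivor set.
Haplotype r^2 is the standard (p11 - p1 q1)^2 / (p1(1-p1) q1(1-q1)),
undefined (error) for monomorphic variants; variants absent from the panel
are treated as unlinked to everything and logged. EFO counting removes
traits mapped to 5 or more terms, counts each term at most once per signal,
normalises as 100 x overlap/total, and ranks only terms with total >= 100.
At desk scale the synthetic catalog has ~25 signals, so the ranking list is
empty by construction - the threshold is kept at its stated value rather
than scaled down.

## Allelic imbalance

The per-variant model on the 2 x R count table has one fixed effect per
replicate plus one allele effect (natural-log scale internally, reported as
log2 alt/ref), shared NB dispersion across the two alleles, fit by
alternating Newton updates (40 sweeps) with the same profile-ML dispersion
machinery (Cox-Reid determinant via the Schur complement of the
(R+1)-parameter information). The standard error of the allele effect comes
from that Schur complement. The test is a threshold Wald against the null
|beta| <= log2(55/45): W = (|beta| - theta)/se when |beta| exceeds theta,
else 0, p = 2 Phi(-W) capped at 1. The one-sided phrasing of the original
criterion combined with the design formula is read as the
greater-in-absolute-value band test (the behaviour of lfcThreshold-style
testing); a strictly one-sided variant is available by flag. The two read
filters (>= 20 total, >= 3 per allele) are applied jointly within a
replicate, with the strictly-more-than-half rule counted over jointly
qualifying replicates; the alternative reading (>= 20 summed over
replicates) is available via `mode="summed"`. A normal reference is used
here (not t): the threshold null is already strongly conservative, and
calibration under pi = 0.5 is verified by simulation (q < 0.05 fraction
<= 0.01 at 2,000 variants).

## Synthetic world

The generator's defaults are the stated smoke-study conditions: 2,000
disjoint 400-bp peaks on a 2 x 10 Mb toy genome, 3 days x 5 ATAC
replicates, NB dispersion 0.05, baseline mean ~150 (log-normal), 25% of
peaks planted with |LFC| = 2 in a 35/35/10/20 class split, per-replicate
peak calls jittered by N(0, 20 bp) and dropped with probability 0.1 plus
100 narrow noise calls per replicate, per-sample GC bias exp(c_j * g(gc))
with c_j ~ N(0, 0.5), RNA at 6/6/4 replicates with 20% of 200 genes planted
at |LFC| = 4, a 200-haplotype panel of 8-variant LD blocks (founder-copy
with 5% per-variant mutation), 25 GWAS leads at p = 10^-U(10,30) with
weaker proxy records, Hi-C/eQTL links planted into context-dependent peaks
(other ends as sub-intervals of the peak; whole LD blocks relocated inside
target peaks so the lead itself is the in-peak variant and overlap truth
survives any sampled r^2), and 400 heterozygous variants at depth ~NB(60)
with 10% planted at an 80:20 allelic ratio. One master seed drives
independent child RNG streams per component in a fixed spawn order, so runs
are byte-deterministic.

The geometry is deliberately clean: peaks are disjoint with generous gaps,
TSSs, bait fragments and non-planted panel variants sit clear of all peaks,
and noise peak calls are too narrow to bridge adjacent true peaks. This
makes the merged test-set regions map one-to-one onto true peaks and makes
link/overlap recovery exactly checkable against ground truth. It also means
a green test does NOT establish behaviour on overlapping peak calls,
ambiguous fragment-to-peak assignments, correlated LD between distant loci,
reference-mapping bias in allele counts, or any read-level artefact - read
trimming, alignment, peak calling, WASP remapping and count extraction are
all upstream of this package's scope.

Two scope notes on the pipeline driver. Read-level quantification is out of
scope, so the emitted count matrix is keyed by true peak ids and `run_all`
maps merged test-set regions back to true peaks by largest >= 1 bp overlap
(one-to-one under the generator's geometry; unmapped or multiply-mapped
regions are dropped and counted in the report). And the exact link-recovery
check feeds the generator's truth DE table into the DE-evidence step:
recomputing DE from the simulated RNA counts is itself stochastic, and the
check is meant to verify the linking logic, not the DE caller (whose error
control is tested separately); `run_all` always recomputes DE from counts
for its report. QC in `run_all` is reporting-only: the simulated inputs
already represent post-QC libraries, so failing a QC rule does not drop a
library from the downstream matrices.

## Known limitations

- Dispersion estimation is per-feature ML without information sharing;
  at very low counts (mean < ~5) the t-referenced Wald can be conservative.
- The GC quantile map is estimated per sample with ~n/10 features per bin;
  below ~100 features the factors are noisy and the bin count is reduced
  with a warning.
- `ld_clump` is quadratic in catalog size within the position window;
  adequate for clumped desk-scale catalogs, not for a full 100k-row
  catalog without windowed indexing.
- The AI model assumes a common dispersion for both alleles of a variant
  and independent replicates; technical replicate correlation would
  inflate significance.
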