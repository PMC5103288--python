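# Methods

This note documents the statistical models, conventions, defaults, and known
limitations of `mycopop`, in the spirit of the methods documentation of
established population-genetics packages.

## Synthetic cohort generator

The generator exists so every estimator in the pipeline can be tested
against known truth; it is first-class, tested code, not a fixture.

**Model.** Balding–Nichols: per locus, an ancestral frequency p is drawn
uniformly on `ancestral_freq_range` (default [0.05, 0.95]); population j
draws its frequency from Beta(p(1−c_j)/c_j, (1−p)(1−c_j)/c_j). The
parameter c_j is exactly the quantity Weir–Cockerham θ estimates, which is
why this model was chosen over a coalescent: the target of every downstream
estimator is a direct input. A configurable fraction of loci is "planted"
at an elevated shared c (default 0.6) to emulate selection outliers.
Diploid genotypes use inbreeding-adjusted Hardy–Weinberg probabilities
{p² + Fp(1−p), 2p(1−p)(1−F), (1−p)² + Fp(1−p)}. Hybrid strains draw one
allele from each of two named parent populations, producing the excess
heterozygosity (negative F) characteristic of between-group hybrids.

**Defaults as study conditions.** The defaults mirror the shiitake
resequencing cohort the package was designed around: 3 populations of
26/6/26 strains plus 2 hybrids (60 total); per-population divergence
c = (0.40, 0.25, 0.22), chosen by solving the pairwise relation
F_ST(j,k) ≈ (c_j + c_k)/2 against the observed pairwise window F_ST scale
0.33/0.31/0.23; inbreeding F = (0.39, 0.45, 0.20), the observed per-group
values; 8 scaffolds × 400 kb with 20,000 loci (≈ 6 SNPs/kb, the real
cohort's density); MAF floor 0.05 matching the site filter. Loci failing
the cohort-wide MAF floor are redrawn in place, at most 100 attempts, then
error — never silently dropped. One global seed; each stage (genotypes,
annotation, phenotypes) derives its own generator deterministically so
stages can be rerun independently.

**Annotation and phenotypes.** Non-overlapping gene intervals (default 800
genes × 1.5 kb) are spaced evenly with jitter; genic SNPs are missense with
probability 0.3 (the cohort's missense/(missense+synonymous) fraction),
else synonymous. Each gene carries 1–5 GO terms from a pool of 50; a
configurable number of "enriched" terms attaches preferentially (80 % vs
5 % background) to genes whose missense SNPs are private-ish to one
population (minor allele convincingly present, frequency in (0.1, 0.9), in
exactly one group), so over-representation tests have planted signal.
Phenotypes are global mean (10) + per-group shift + N(0, 1) noise, with
shifts of ±3σ for 11 of the 13 traits and zero shift for NF and SL,
mirroring a cohort where almost all traits are stratified by structure;
2 % of cells are masked missing at random.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium beyond positional
thinning (loci are independent), demographic history (no drift
trajectories, bottlenecks, or migration), sequencing error and depth
variation (the VCF writer emits uniform DP 50, QUAL 999), multi-allelic
sites, and indels. Tajima's D on this generator does not center at zero
because the frequency spectrum is beta, not coalescent; its sign behavior
(negative under excess rare variants) is still testable.

## Site filters and group membership

Filters replicate the study design: biallelic SNPs, QUAL ≥ 30, mean depth
≥ 5, no missing genotype, allele-count MAF ≥ 0.05 (inclusive, computed
over 2N called alleles rather than genotype frequencies, the VCF-convention
frequency filter). "Mean depth" averages per-sample DP over non-missing
samples; the denominator is not standard anywhere, and non-missing avoids
penalizing missingness twice. Thinning is the conventional greedy
left-to-right pass per scaffold (keep first locus; keep the next iff ≥
1,000 bp beyond the last kept). A locus is "detected in a group" when both
alleles are observed among that group's strains (polymorphic-within-group);
the alternative alt-allele-present rule is available behind the `rule=`
switch since published per-group SNP counts do not disambiguate the two.
Coordinates are 1-based inclusive throughout.

## Diversity statistics

- **Site π** uses the unbiased pairwise estimator 2p̂(1−p̂)·2N/(2N−1) over
  called alleles; **window π** divides the summed site π by the window
  length in bp (per-bp diversity, the VCFtools `--window-pi` convention),
  on 5-kb windows tiled from position 1. This convention was chosen because
  the motivating study reports per-bp values of order 10⁻³.
- **Tajima's D** uses the standard 1989 constants with n = 2N sampled
  alleles; undefined (NaN) when a window has no segregating site; refused
  for n < 4 where the variance constants degenerate.
- **Inbreeding F** is the observed-vs-expected homozygosity form
  (No − E[hom])/(L − E[hom]) (the VCFtools `--het` convention), with E[hom]
  from the pooled frequencies of whatever strain subset the matrix holds —
  pass a per-group subset to estimate F "within a group". Whether published
  per-group tables pooled expectations per group or cohort-wide is
  ambiguous; within-the-listed-grouping is the default here.
- **AMOVA** treats each strain as two allele-observations (alt indicators),
  accumulates sums of squares over loci at three levels, and solves
  E[MS_w] = σ²_w, E[MS_s] = σ²_w + 2σ²_s, E[MS_p] = σ²_w + 2σ²_s + n₀σ²_p
  with n₀ = (A − ΣA_k²/A)/(P−1) over allele-observation counts. Negative
  components are reported as-is with a warning, not truncated. Report
  rounding: 2 decimals (ratios: 3), matching conventional table precision.
  Strains labeled "outlier" (hybrids) are excluded.

## Phylogeny

The distance is the allele-sharing dosage distance mean|g_i − g_j|/2 — the
historical analysis names its tree program but not its metric, so the
metric is an explicit, configurable choice here. NJ is the Saitou–Nei
algorithm with the standard Q criterion; exact ties break on the
lexicographically smallest taxon pair, making output independent of input
order (verified by property test). Negative branch lengths, possible on
non-additive inputs, clamp to zero with a warning. Outgroup rooting places
the root at the midpoint of the outgroup's pendant edge. Bootstrap support
is locus resampling with a seed; support = fraction of replicates
recovering the bipartition.

## Divergence scan

Site F_ST is Weir & Cockerham (1984) with heterozygote frequencies in the
b/c components. Note the estimator is unbiased but not positive: for two
identical samples the realized a is slightly negative (zero only in
expectation); θ may be negative and is NaN where a+b+c = 0. Windows
aggregate by ratio-of-sums (the weighted VCFtools windowed convention, not
mean-of-ratios). Top-window selection is nearest-rank: the ⌈f·N⌉ highest-θ
windows among defined windows, all cutoff ties kept (tie handling is not
specified anywhere authoritative; inclusion is the deterministic choice).

The outlier scan is a desk-scale re-implementation of the
multinomial-Dirichlet logistic model — not a wrapper around the external
program, whose exact numbers it does not promise to replicate. Priors:
α ~ N(0, 2) (covers F from ~0 to ~0.98 given typical β), β ~ N(−1, 1.8),
p ~ U(0,1); prior odds 10 for the neutral model. The sampler is a
reversible-jump MCMC whose birth proposal equals the α prior (so prior
terms cancel in the acceptance ratio); locus-level updates are vectorized
across loci, which are conditionally independent given β. Defaults: 5,000
burn-in + 20,000 kept iterations, thinning 10; proposal widths are
pilot-adapted during burn-in toward 20–45 % acceptance. Convergence is
monitored by split-half agreement of inclusion probabilities (warn above
0.1 disagreement). q-values are running means of sorted PEPs, ties sharing
the highest tied value. Outlier calls require q < 0.05 AND posterior locus
F_ST (not α) above the scan mean — the published filter's "coefficient" is
ambiguous between the two; posterior F_ST is the natural scale.

**Operating characteristics.** On the planted-outlier benchmark (1,000
neutral loci at c = 0.1, 50 planted at c = 0.6, 3 populations × 20
strains), calling at q < 0.05 is strongly conservative: realized FDR ≈ 0
and power ≈ 0.4. This is a property of the information in the design, not
of the sampler: the exact (quadrature) posterior for the same model gives
the same calls, and about half of the Balding–Nichols c = 0.6 loci simply
do not realize enough between-population divergence across only three
populations to be distinguishable from background at that threshold. With
more populations or larger samples the same scan sharpens quickly; see the
acceptance suite for measured values.

Candidate assignment: an outlier SNP supports the divergence of group X
iff it lies in a top-5 % F_ST window of BOTH pairwise comparisons
involving X; membership in all three pairs assigns all three groups;
membership in ≤ 1 pair assigns nothing but is kept in the per-pair tally.
Assignment is order-invariant (property-tested). Genes come from the SNP
annotation; per-group lists are deduplicated, with a sharing report.

## Enrichment

Group-specific SNPs are loci detected in exactly one non-outlier group
(sets are disjoint by construction). Missense ones map to genes; each GO
term gets a one-sided hypergeometric tail P[X ≥ k] against the background
of all genes carrying ≥ 1 analyzed SNP. Plain Fisher only — no GO-graph
decorrelation ("elim"/"weight") and no ancestor propagation; both are
deliberate scope cuts, and annotations are taken as given. No
multiple-testing correction on the starred calls (0.05/0.01); a
Benjamini–Hochberg column is emitted as a clearly optional extra. The
effect size is log₂((k/n)/(K/N)), NaN when k or K is zero.

## Phenotypes

Min–max normalization per trait over non-missing values; constant traits
map to zero with a warning; missing stays missing. Clustering is complete
linkage on Euclidean distances for both strains and traits (scipy
implementation; merge heights are non-decreasing, property-tested), with
trait-mean imputation for missing cells — imputed cells are flagged in the
output since the choice of imputation is not canonical. Post-hoc
trait-difference testing is out of scope; the per-group mean/SD summary
supports the same comparisons descriptively.

## Pipeline

Stages run in fixed order (simulate/read → filter → thin → diversity →
structure → divergence/scan → enrichment → phenotypes); every output file
is listed in a JSON manifest with SHA-256 hashes, and identical
config + seed reproduces identical hashes (tested). AMOVA runs on the
thinned marker set, matching the original study's choice of marker panel
for structure-level analyses. Failures abort with the stage name and keep
partial outputs. The CLI (`mycopop simulate|run|report`) is a thin layer
over `mycopop.pipeline`; exit codes are 0/1/2 for ok/config error/stage
failure.

## Problem sizes in the test suite

Unit tests run on hand-built fixtures and cohorts of a few hundred to a
few thousand loci. The heavier checks use: 5,000 neutral loci for F_ST
parameter recovery (±0.03 of c = 0.25); 1,050 loci × 5 seeds at full
default chain length for scan operating characteristics; 300 loci × 20
seeded runs at 5,000 iterations for the null control; 50 random fixtures
per statistic for the 1e-9 oracle-equivalence suites. These sizes were
chosen as the smallest at which each property is statistically stable.
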