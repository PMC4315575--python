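# Methods

## Mapping model

The mapping procedure treats each inbred strain as a single homozygous
genotype and the strain-level phenotype mean as one observation.  For a
haplotype block that partitions the n phenotyped strains into k groups,
the association statistic is the one-way ANOVA F with (k−1, n−k)
degrees of freedom; p-values come from the F distribution.  The genetic
effect size,

    effect = (SSB − (k−1)·MSE) / (SStot + MSE),   MSE = SSW/(n−k),

is an unbiased-flavoured variance-explained measure: it subtracts the
(k−1)·MSE expected contribution of group-mean estimation and is bounded
above by 1, attained exactly when within-group variance vanishes.
Because each strain contributes one observation, the test captures the
between-strain genetic signal but cannot model within-strain replicate
error or kinship between strains; population-structure correction
(mixed-model style) is deliberately out of scope.

Degenerate cases are resolved explicitly: a constant phenotype gives
F = 0, p = 1 and effect 0 (SStot + MSE = 0 makes the ratio 0/0; there is
no variance to explain); perfect separation (SSW = 0, SSB > 0) gives
F = ∞, p = 0 and effect 1; a block in which every group is a singleton
(n = k) has no within-group variance estimate and is skipped with a
logged reason rather than ranked.

## Variant filtering

A per-strain variant call is accepted as a definitive alternative
allele when QUAL ≥ 50, the GT is homozygous-alternative, and the PL of
the homozygous-alternative genotype is at least 20 units below every
other listed genotype likelihood (both thresholds inclusive, so
QUAL = 50 and gap = 20 pass).  Any failure demotes the call to N with
the first failing rule recorded; rules are evaluated in the order QUAL,
GT, PL-gap.  Matrix assembly takes the union of sites across strains,
codes strains without a record at a site as reference (a variant caller
emits records only where a variant is supported; the N conversion
applies to *failing variant calls*, not to absent ones — this reading is
a documented choice), and drops indel sites, sites with more than one
distinct alternative allele, and sites left with no definitive
alternative call.

## Block construction

Blocks are built per haplotype count k ∈ {2..5} as maximal runs of
consecutive eligible SNPs on one chromosome whose fully-called strains
show exactly k distinct allele strings.  Eligibility requires the SNP
to be polymorphic among the phenotyped strains and to have at least
min(8, ⌈n/2⌉) unambiguous calls (the ⌈n/2⌉ branch serves panels smaller
than 16 strains; the threshold is configurable).  An ineligible SNP
breaks contiguity: blocks never span it.  This maximal-run scheme is a
reimplementation of the dynamic construction idea — it preserves the
defining property (blocks of 2–5 haplotypes tiling the genome, emitted
independently per k, single-SNP blocks allowed) and is deterministic,
but it is not guaranteed to be call-for-call identical to earlier
implementations of the approach.

Strains with an N inside a block interval do not participate in
defining the haplotypes; they are assigned afterwards to the unique
haplotype compatible with their non-N alleles, or marked EXCLUDED when
zero or several haplotypes match.  Because dropping a partially-called
strain can make the distinct-string count non-monotone in interval
width, the scan from each left endpoint stops the first time the count
exceeds the k ceiling (or fewer than two strains remain fully called)
and does not look for re-descending intervals beyond that point; with
no missing data this reduces exactly to the monotone case.  Left-
maximality is decided against the previous endpoint's scan under the
same horizon rule, which keeps the construction deterministic.

## Gene aggregation, filtering, robustness

A block is attributed to every gene whose annotated interval overlaps
the block's genomic span; each gene keeps its best block (smallest p
for numeric traits, largest F for categorical ones, with larger F
breaking p ties).  Categorical traits are integer-coded in order of
first appearance and scored by the same one-way ANOVA, ranked by F —
one admissible reading, since the original encoding is not pinned down.
Candidates are then restricted to genes that are expressed in the
designated target organ *and* carry a missense SNP, and sorted with a
lexicographic gene-symbol tie-break for determinism.

The robustness assessment reruns the scan 100 times after deleting
d ∈ {1,2,3} strains (d uniform, strains uniform without replacement),
discarding and redrawing any subset already seen; it errors upfront if
fewer distinct subsets exist than iterations (C(n,1)+C(n,2)+C(n,3)).
Per gene, score = Σ −log₁₀(pᵢ) with pᵢ censored at the cutoff (0.01)
whenever the gene's p exceeded it *or the gene was absent from that
iteration's results* — both are treated as censored, since a gene
missing from the filtered output carries no more evidence than a
censored one.  p = 0 is capped at a configurable floor of 1e-300 to
keep scores finite.

## Strain trait statistics

Trait–trait screens use Spearman's rho (robust to non-normal,
outlier-prone latency data; invariant under monotone transforms such as
log₁₀) with Benjamini–Hochberg adjustment across exactly the batch of
pairs tested in one call.  Confirmatory two-group comparisons log₁₀-
transform the measurements, apply a two-sample t-test (pooled variance
by default, Welch optional — the pooled form is the classical default
for small balanced groups), and back-transform the difference and its
95% CI through 10^x to a fold change.

## Human cohort analysis

Ordinal toxicity scores (0 absent … 3 severe) for parkinsonoid,
dyskinesia and akathisia are collapsed per day into a combined
indicator: 1 if any score ≥ 2, 0 if all three are present and ≤ 1, NA
otherwise (a missing score with no score ≥ 2 cannot certify either
state).  The cumulative index sums the indicator over days {0,1,3,7},
so it counts toxic days (0–4); any NA day makes the index NA and the
patient is excluded listwise from association and permutation.

SNPs are screened by a 1-df chi-squared goodness-of-fit test of
genotype counts against Hardy–Weinberg expectation from the sample
allele frequency; monomorphic SNPs are flagged and excluded.  SNPs with
all three genotypes are tested by an additive linear model (minor-allele
dosage 0/1/2; p from the 1-df slope F test, the standard reading of an
additive ANOVA); SNPs with two observed genotypes by a pooled
two-sample t-test, which coincides with the slope test for a
binary-valued regressor.

The minP correction permutes the cumulative index across patients
while genotypes stay fixed — preserving the linkage disequilibrium
among SNPs — recomputes every raw p per permutation, and records the
minimum.  The adjusted p for SNP j is the proportion of permutation
minima ≤ the observed raw pⱼ, floored at 1/n_perm so the permutation
resolution is respected; an add-one (k+1)/(n+1) estimator is available
as an option since either convention is defensible at 1,000
permutations.  Comparisons use ≤, which is conservative under the
heavy ties a 0–4 index produces.

The binomial enrichment calculation reports both the point probability
C(m,k)·αᵏ·(1−α)^(m−k) and the upper tail P(X ≥ k) that k of m
independent tests fall below α.

## Synthetic-data generators

The panel generator cuts the genome into fixed-length segments
(default 50 SNPs) and lets each strain draw one of a small number of
ancestral haplotypes (default 4) per segment independently — the
simplest mosaic that produces realistic block boundaries.  A causal
block (defaults: 10 SNPs wide, 3 groups of sizes 14/2/1, group means
20/158/234 s, group SD 15 s, matching a latency-like trait with one
extreme strain) overwrites the mosaic inside a single segment with
distinct per-group allele strings whose every column is polymorphic; a
block crossing a segment boundary is rejected, since recombination
would break it.  Phenotypes are group mean + Gaussian noise truncated
at zero (latency is non-negative), one value per strain with MPD-style
sd/n columns filled for format fidelity.  Gene annotations tile the
site range into 50 genes; the single gene containing the causal block
is flagged missense + target-organ-expressed, other genes draw flags at
random (50% expressed, 30% missense) so that ranking — not just flag
filtering — distinguishes the causal gene.  Calls are masked to N at a
2% default rate.

The variant-call generator enumerates a fixed truth table covering
every filter branch (QUAL below/at/above threshold, het and hom-ref
GTs, PL gap below/at/above threshold, multi-allelic, indel) and writes
it as a VCF v4.2 with the expected verdict attached to each record.

The cohort generator draws two haplotypes per patient from a latent
Gaussian copula — independent across SNPs except within declared LD
blocks, where a shared factor induces the configured correlation — and
thresholds at the MAF quantile, so genotype sums are Hardy–Weinberg by
construction.  Defaults mirror the motivating cohort: 85 patients, 29
SNPs in three LD blocks, assessment days {0,1,3,7,14,21} with per-day
availability (85,85,85,85,81,54).  Ordinal scores come from a
cumulative-logistic model on a per-patient latent propensity plus day
effects (toxicity incidence rising to day 14) and, optionally, an
additive causal-dosage term; patients beyond a day's availability count
are missing that day.  What the generator does *not* emulate: real LD
decay within blocks (the copula correlation is exchangeable),
covariates (age, dose, co-medication), informative dropout, and real
allele-frequency spectra — so passing tests demonstrate the
statistical machinery is correct under the stated model, not that the
pipeline reproduces any particular cohort's findings.

All generators derive per-stage random streams from a single config
seed, making every output bit-for-bit reproducible.

## Problem sizes and numerical choices

The recovery experiment uses 100 replicate panels of 17 strains × 2,000
sites with 50 genes; the robustness check uses a 600-site, 20-gene
panel over the full 100 iterations; the null family-wise-error
simulation uses 500 cohorts at 200 permutations each — sizes chosen so
the full suite runs on a laptop in a few minutes while keeping
Monte-Carlo error small relative to the bands being checked.  The
acceptance script uses 50 panels and 300 cohorts for the same
quantities.  Ties in ranking are always broken lexicographically by
gene symbol; permutation comparisons use ≤; all p-value floors and the
censoring cutoff are configurable.

## Known limitations

No kinship or population-structure correction; no phasing or
LD-confidence block definitions; the human arm tests one SNP at a time
(no haplotype tests); the block construction's equivalence to earlier
dynamic-construction codes is property-level, not call-for-call; and
strain panels are assumed fully inbred — heterozygous calls are
filtered to N by design rather than modelled.
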