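# hbcgm

Haplotype-based computational genetic mapping (HBCGM) for inbred strain
panels, with a companion human-cohort association arm for ordinal
drug-toxicity scores.

## The problem

Inbred mouse strains are homozygous, so a single genome sequence
represents every animal of a strain, and a phenotype measured across a
panel of strains can be correlated with the pattern of haplotypes in
genomic blocks.  This package implements that mapping pipeline end to
end for susceptibility-to-drug-toxicity style traits (the motivating
trait is haloperidol-induced latency, measured in seconds):

1. **Variant filtering** (`variant_filter`): per-strain VCF calls are
   accepted as definitive alternative alleles only when QUAL ≥ 50, the
   genotype is homozygous-alternative, and the homozygous-alternative PL
   beats every other genotype likelihood by ≥ 20 units; failing calls
   become `N` (undetermined) rather than reference.  Bi-allelic SNPs with
   at least one definitive alternative call across the panel form the
   strains × sites allele matrix.
2. **Haplotype blocks** (`haplotype_map`): SNPs polymorphic among the
   phenotyped strains with at least min(8, ⌈n/2⌉) unambiguous calls are
   eligible; maximal runs of consecutive eligible SNPs over which the
   panel splits into exactly k ∈ {2..5} distinct haplotypes become
   blocks, with ambiguous (`N`-bearing) strains assigned only when they
   match a unique haplotype.
3. **Association scan** (`hbcgm_scan`): each block is scored by one-way
   ANOVA of the strain phenotype against the haplotype grouping, with
   the genetic effect size

   ```
   effect = (SSB − (k − 1)·MSE) / (SStot + MSE),   MSE = SSW / (n − k)
   ```

   bounded above by 1 (equality iff SSW = 0).  Blocks aggregate to genes
   by interval overlap (smallest p, or largest F for categorical
   traits), and candidates are filtered to genes expressed in a target
   organ that carry missense SNPs, then ranked.
4. **Robustness** (`robustness`): 100 re-runs after randomly deleting
   1–3 strains; per gene, score = Σᵢ −log₁₀(pᵢ) with p censored at 0.01,
   so the floor is 200 over 100 iterations.
5. **Strain trait statistics** (`trait_prep`): Spearman correlation
   screens with Benjamini–Hochberg adjustment, and log₁₀-scale two-sample
   t-tests back-transformed to fold-change estimates with 95% CIs.
6. **Human arm** (`cohort_association`): per-patient ordinal (0–3)
   toxicity scores for three toxicity types over days {0,1,3,7,14,21}
   collapse to a combined daily indicator (toxic iff any score ≥ 2) and
   a cumulative index (AUC ∈ {0..4}, the count of toxic days among
   {0,1,3,7}); SNPs are screened for Hardy–Weinberg equilibrium, tested
   by an additive linear model (or two-sample t-test when only two
   genotypes occur), and corrected for multiple testing by minP
   permutation (toxicity permuted, genotypes — and their LD — fixed).
7. **Synthetic data** (`synthetic_data`): generators for a mosaic
   strain panel with a configurable causal block, a truth-table VCF
   covering every filter branch, and an 85-patient cohort with
   LD-blocked Hardy–Weinberg genotypes and ordinal toxicity scores —
   each with ground-truth labels used by the test-suite oracles.

## Worked example

```python
from hbcgm import (PanelSimConfig, default_latency_block,
                   simulate_strain_panel, run_scan)

config = PanelSimConfig(seed=1, causal_block=default_latency_block())
matrix, phenotype, annotation, truth = simulate_strain_panel(config)
pheno = dict(zip(phenotype["strain"], phenotype["mean"]))
ranked = run_scan(matrix, pheno, annotation, target_organ="brain")
top = ranked[0]
print(top.gene, truth.causal_gene, f"p={top.p:.3g}", f"effect={top.effect_size:.3f}")
```

prints

```
Gene002 Gene002 p=9.58e-09 effect=0.914
```

— the gene containing the simulated causal block ranks first; its ANOVA
p-value (9.6 × 10⁻⁹ here) reflects the three latency groups (means
20/158/234 s, SD 15 s) across 17 strains, and the genetic effect size of
0.91 says the haplotype grouping explains most of the phenotypic variance.

The same pipeline is available from the shell:

```bash
hbcgm simulate panel --seed 1 --out panel/
hbcgm scan --matrix panel/matrix.tsv --pheno panel/phenotype.tsv \
           --annot panel/annotation.tsv --organ brain --out results.tsv
```

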