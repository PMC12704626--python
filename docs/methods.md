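# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of the `stratwas` pipeline.

## Generative model

**Genotypes.** Each locus is an independent LD block of `n_variants`
variants on its own chromosome. Per haplotype, a latent AR(1) Gaussian
process with adjacent correlation `ld_rho` is thresholded at Φ⁻¹(MAF) to
produce alleles; the two haplotypes sum to a 0/1/2 dosage. This copula
gives exact control of both allele frequency and LD decay. At the default
`ld_rho = 0.8` the realized genotype correlation of adjacent variants is
≈ 0.72 (thresholding attenuates the latent correlation), which populates
the intermediate-LD window that LD-aware procedures (HEIDI eligibility,
r² > 0.8 proxy expansion) assume real cis regions to have — a sparser
default would make those procedures structurally inapplicable rather than
merely less powered. MAFs are drawn uniformly from `maf_range`
per ancestry; ancestries share positions and alleles and differ only in
frequency draws and seed, which is the minimal structure needed to exercise
the cross-ancestry consistency rule (no admixture or differential LD).

**Expression.** Each gene belongs to one locus and one of seven brain cell
types (Ast, Exc, Inh, Mic, Oli, Opc, End) and regulates two adjacent cis
variants, placed away from block edges so the instrument has flanking LD
proxies on both sides as real cis variants do. Weights are normalised so
the standardized genetic score has approximately unit variance (Monte-Carlo
normalisation under the same copula); the latent expression is
√h²_cis · (Xw) + √(1−h²_cis) · ε, so `h2_cis` (default 0.2, a typical
strong cis signal) is the genetic variance fraction. Pseudobulk counts are
negative binomial with log-mean = library offset + latent and dispersion
`nb_dispersion` (default 0.3); genes are measured in every cell type but
carry their eQTL signal only in their own cell type (pure noise elsewhere),
so cell-type specificity is testable.

**Phenotype.** Disease is Bernoulli with
logit = intercept + Σ β_g · latent_g, the sum running over genes causal in
the subject's stratum ("both" genes contribute in both strata). The default
β = ±0.2 on a unit-variance latent corresponds to ≈ 1.2% of liability-scale
variance per causal gene — comfortably above the 0.5% floor used in the
recovery benchmark and giving per-gene TWAS |z| ≈ 5–6 at 20,000 subjects
per stratum, i.e. detectable but not trivial. The quantitative pathology
score is the same genetic burden plus unit Gaussian noise. Covariates (sex,
age, post-mortem interval, batch, APOE2 dosage) are generated independent
of genotype: they exercise the adjustment code paths, not confounding.

**Default study conditions.** 12 loci × 30 variants; 60 genes, of which 10
(one per leading locus, alternating strata at `stratum_specificity = 1`)
are causal; 20,000 subjects per stratum in the primary ancestry and a
quarter of that in the secondary; a 400-subject mixed-stratum reference
cohort with paired genotypes and pseudobulk counts (emulating a
snRNA-seq + WGS resource) supplies eQTL statistics, expression weights, LD
matrices and the differential-expression data.

**Auxiliary files.** Peaks are 500 bp intervals centred on each gene's
eQTL variants, labelled with the gene's cell type, plus random decoy peaks.
Compound gene sets contain three causal genes of one stratum *and their
druggable interaction partners* plus one null gene — drug-signature
databases list compound targets over a gene network, and the enrichment
stage queries the network-expanded gene list, so sets seeded with isolated
genes would understate the overlap structure the method relies on. Decoy
compounds draw only null genes. The druggable list holds all causal genes,
half the null genes, and the first interaction partner of each causal gene.

## What the generator does not emulate

Realistic human LD panels (long-range structure, the MAPT-like inversions
that defeat colocalization in practice), relatedness and population
stratification, imputation uncertainty, cell-type proportion shifts,
batch-confounded expression, proxy-phenotype misclassification, and
polygenic background outside the simulated loci. Passing tests therefore
demonstrate that the *procedures* are implemented correctly and behave as
designed under their own assumptions — not that the pipeline would be
similarly well calibrated on real consortium data.

## Statistical components and numerical choices

**GWAS.** Plain per-variant logistic maximum likelihood (batched Newton
with stacked normal equations; convergence at max |step| < 1e-8, 30
iterations), in place of the mixed models a real analysis would use — the
synthetic data contain no relatedness. Monomorphic variants are excluded;
non-converged or singular fits keep their row with missing statistics.
Wald z with normal two-sided p. Allele harmonization matches (A1,A2) or the
swap with sign/frequency flip; strand-ambiguous A/T and C/G pairs are
dropped; duplicate keys keep the first occurrence and are logged.

**Effective sample size.** N_eff = 4·N·v·(1−v) with v the case fraction;
the proxy-cohort division by 4 is applied per cohort before any summation.

**Heritability screen.** Permutation p of the maximum squared marginal
correlation across cis variants (500 permutations in the pipeline, seeded).
A permutation screen was chosen over a variance-component fit because it is
exact under the null, assumption-light, and cheap at desk scale.

**Weight fitting.** Candidates are `top1` (best marginal eQTL alone) and
ridge over all cis variants with the penalty chosen on a grid
(0.1…1000) by 5-fold CV. The top1 candidate is re-selected inside each
training fold — selecting it on the full data leaks the test fold and
inflates null CV R². A candidate must exceed CV R² = 0.01 to win: exactly
zero would let heavily-shrunk near-constant ridge predictors, whose CV R²
fluctuates at ±ε, pass null genes by chance. Genotypes are mean-imputed and
standardized; weights are reported on the standardized-genotype scale.

**TWAS.** z = wᵀz_GWAS/√(wᵀRw) with R the in-sample reference LD (as in
single-cohort practice); wᵀRw < 1e-8 yields a missing result rather than a
blow-up. The null distribution is mildly heavy (empirical sd ≈ 1.1) because
fitted weights and in-sample LD are noisy — visible in the recovery
benchmark as occasional opposite-stratum p ≈ 0.05 flukes.

**FDR.** Benjamini–Hochberg, pooled across all (cell type, gene) pairs
within each stratum — the stricter and simpler reading versus per-cell-type
correction; configurable.

**Heterogeneity and locus rules.** Implemented literally: criterion (2)
(opposite direction) does not require the opposite stratum to be
non-significant. "Most significant gene" of a locus is the smallest p over
both strata, ties broken by smaller q then gene id (logged). Locus reach is
TSS-to-TSS single linkage at 1 Mb, which on a line reduces to chaining
adjacent gaps ≤ 1 Mb. "Improved" cross-ancestry p means strictly smaller.

**Colocalization.** Wakefield lABF = ½log(V/(V+W)) + (z²/2)·W/(V+W) with
prior effect SDs 0.2 (log-odds trait) and 0.15 (quantitative trait). All
hypothesis sums run in log space (log-sum-exp), so |z| > 40 cannot
overflow. Two prior schemes: default (p1 = p2 = 1e-4, p12 = 1e-5) and an
adjusted scheme with p12 = 1e-4 reflecting that tested pairs are
pre-selected TWAS discoveries; the best PP4 across schemes is tiered at
0.4/0.7. The "top colocalizing variant" is the largest per-variant share of
the shared-variant hypothesis (largest lABF₁+lABF₂).

**SMR / HEIDI.** T_SMR = z²_G z²_E/(z²_G+z²_E), p from χ²(1); b_xy =
b_G/b_E at the top cis eQTL. HEIDI eligibility: eQTL p < 1.57e-3 and r²
with the top SNP in [0.05, 0.9], at most 20 SNPs, at least 3 (else the
p-value is missing and, by default, missing HEIDI does not count as
support). The covariance of the b_xy differences comes from the delta
method with LD-induced correlation within each trait (traits independent
across cohorts); the null of Σz²_d is simulated from the implied
multivariate normal (10⁴ seeded draws; a singular correlation is
ridge-regularized by 1e-8 with a warning).

**Pseudobulk DEG.** TMM with the conventional trims (30% per M tail, 5%
per A tail), inverse asymptotic binomial-variance weights, reference =
library whose upper-quartile nonzero CPM is closest to the mean, factors
rescaled to geometric mean 1. Expression is log₂-CPM with a 0.5 pseudocount
over TMM-scaled libraries; inference is per-gene OLS with a t-test on the
phenotype coefficient — empirical-Bayes variance moderation is deliberately
omitted so the fit is exactly checkable against a closed form. The "≥1.5
larger" stratified clause is multiplicative (|logFC_s| ≥ 1.5·|logFC_other|);
an additive reading was rejected because pseudobulk effects are fractions
of a log₂ unit. A pair is DEG-supported if the rule holds for ≥1 phenotype
(AD status or pathology score; configurable to require all).

**Prioritization and drugs.** Six layers, missing layers count false.
"At least half" = ≥3 and "more than half" = ≥4 of 6; the drug stage uses
the ≥4 tier by default. Network expansion is a single hop, keeping only
druggable neighbours (seeds kept regardless). Enrichment is a one-sided
hypergeometric over the universe of all genes in the GMT database plus the
annotation, BH-corrected; the ≥2-gene robustness filter counts prioritized
(seed) genes by default, with the expanded-query interpretation available
via a parameter.

## Problem sizes

The test suite and acceptance script run everything at the sizes stated
above (the package's own validation conditions): the full pipeline once at
20,000 subjects/stratum; null calibrations at 200 replicates of reduced
size (n = 50–1,500); discrimination at 50 replicates of n = 20,000 single
loci; kernel-vs-oracle checks at 100–1,000 random instances. End to end
this completes in a few minutes on one CPU.

## Known limitations

In-sample LD and fitted weights inflate the TWAS null slightly (sd ≈ 1.1),
so opposite-stratum chance significance removes ~1 causal gene per run at
the default conditions — the recovery benchmark's ≥80% margin absorbs
this, and it mirrors the behaviour of the real procedure. HEIDI's p-value
is missing for instruments whose LD neighbourhood is too sparse; such pairs
can never gain SMR support under the default (no-waiver) rule. The two ABF
prior schemes stand in for the original best-of-three that also included a
multi-signal (SuSiE-based) colocalization; loci with several causal
variants are therefore outside this implementation's reach.
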