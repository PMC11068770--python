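# Methods

## Problem setting

A diversity panel of inbred accessions (the motivating case is a lentil
herbicide-tolerance panel: ~292 accessions, ~7,600 biallelic chip SNPs on 7
chromosomes) is phenotyped in several environment × treatment combinations.
Trials are unbalanced: not every accession appears in every context, traits
differ between locations and seasons, and the same panel recurs across
contexts. The goal is to find marker–trait associations that are supported
jointly by the environments while accounting for the fact that repeated
measurement of one panel does not provide independent evidence.

## Phenotype derivation

Replicate observations are averaged per accession within each
(environment, treatment, trait) context. Herbicide tolerance is expressed
by the reduction index

    RI = 100 − 100 · T̄ / C̄

where T̄ is an accession's mean under herbicide and C̄ its own mean in the
untreated control of the same environment. RI is computed per accession
(not from context grand means); it is scale-invariant, monotone decreasing
in T̄, and may be negative when a treated plot outperforms its control. A
zero or missing control propagates a missing RI rather than an error.
Herbicide damage scores (ordinal 1 = no damage … 5 = total mortality) are
validated to the 1–5 range and analysed as quantitative values — no ordinal
model is fitted. Contexts enter the scan only with ≥ 30 non-missing
phenotypes (a guard against degenerate fits).

## SNP quality control and kinship

Three rules are evaluated simultaneously on the raw matrix: call rate
strictly > 0.80, MAF ≥ 0.05, heterozygosity ≤ 0.15 (heterozygous calls in a
selfing crop are mostly technical artefacts). Boundary semantics are
deliberate: a call rate of exactly 0.80 fails, a MAF of exactly 0.05
passes. Because all rules are applied in one pass to the input statistics,
the filter is idempotent. The genomic relationship matrix is the VanRaden
form K = ZZ′ / (2 Σ fᵢ(1−fᵢ)) with per-SNP mean imputation of missing
dosages; under Hardy–Weinberg sampling its diagonal averages ≈ 1.

## Single-context mixed model

Per context, y = μ + xb + g + e with g ~ N(0, σ²_g K) and e ~ N(0, σ²_e I).
The variance ratio λ = σ²_g/σ²_e is estimated once on the null model by
REML: after rotating by the eigenvectors of K the covariance is diagonal
with weights λsᵢ + 1, and the profiled criterion is minimised on a 61-point
log-spaced grid over [1e−5, 1e5] refined by bounded scalar search —
deterministic, no random restarts. λ is then fixed for all SNPs (the
EMMAX-style approximation; re-optimising per SNP changes nothing material
at these scales and costs orders of magnitude more). Each SNP is a
weighted two-column regression in the rotated basis; the residual variance
is re-estimated per SNP with n − 2 df; the Wald statistic t = b/se uses a
standard-normal reference so t² is a 1-df chi-square, which the
meta-combination assumes. Missing dosages are mean-imputed within the
context; SNPs monomorphic within a context yield missing results (counted,
not dropped silently). No covariates or principal components are included.

Numerical notes: eigenvalues of K are clipped at zero (tolerance −1e−8
relative); a SNP is declared monomorphic when its intercept-projected
variance falls below 1e−10; the stored `loglik` is the ML log-likelihood at
the REML λ̂ (so with K = I it reduces exactly to the iid-normal
likelihood), while the optimised restricted criterion is kept as
`reml_loglik`.

## Meta-combination across environments

For one trait with t-values t over n contexts, the statistic is
χ² = t′V⁻¹t with V the correlation matrix of t-values between contexts
estimated across all SNPs (pairwise-complete, with a configurable floor of
100 shared SNPs per pair). It is referred to a chi-square with df equal to
the number of contexts the SNP was actually tested in: SNPs missing in some
contexts use the matching submatrix of V and reduced df rather than being
dropped — this is what "unbalanced" requires. If V is not positive
definite it is shrunk toward the identity by the smallest factor restoring
a minimum eigenvalue of 1e−6 (this preserves the unit diagonal, unlike
eigenvalue clipping; the repair is flagged). V is estimated over all SNPs,
including the rare true associations, as in the source methodology.

Significance: Bonferroni, p ≤ α/n with n the number of SNPs tested for the
trait (with 7,642 SNPs and α = 0.05 the cut is −log10 p ≥ 5.18 ≈ 5.2);
associations with p < 1e−4 above the cut are labelled suggestive.

Why the correction matters: with shared accessions, a SNP's chance
correlation with any phenotypic component that persists across contexts
(e.g. a stable polygenic background) repeats in every context, so null
t-values are cross-correlated and the naive Σt² has a heavier tail than
χ²_n even though its mean stays n. The quadratic-form analysis for three
equicorrelated t-values shows the naive type-I rate at nominal 0.05 exceeds
0.07 once the t-correlation passes ≈ 0.6; the validation experiments use
h² = 0.7 with a fully stable background (t-correlation ≈ 0.65) to place
the naive statistic clearly outside the calibration band while the
V-corrected statistic stays inside it.

## QTL windowing and reports

Significant SNPs are grouped per (trait, chromosome) by single-linkage
chaining: position-sorted hits ≤ 1 Mb apart (default, exposed as
`window_bp`) join one cluster, so the cluster count is monotone
non-increasing in the window. Cross-trait colocalization is not merged.
Manhattan tables use running chromosome lengths as offsets; QQ tables pair
sorted observed −log10 p with −log10((i−0.5)/m) and report the genomic
inflation factor λ_GC = median(χ²)/median of the reference chi-square at
the modal df. Zero p-values are clamped to the smallest positive float and
flagged.

## Diversity clustering

Accession distances are identity-by-state: mean allele difference over
pairwise non-missing SNPs (pairwise-complete rather than imputed, to
preserve distance semantics); similarity is 1 − distance. Agglomeration is
complete linkage written out as the classic O(n³) loop with a deterministic
lexicographic tie-break on node ids — scipy's implementation serves as an
independent oracle in the tests rather than the implementation, precisely
so tie behaviour is pinned. Newick export is ultrametric with branch
lengths of half the parent–child height difference (leaf-to-leaf path =
cophenetic height). Flat cuts stop after n − k merges; the number of
clusters is a user parameter, not inferred.

## Synthetic-data generator

The generator is first-class, tested code and defines the validation
conditions. Defaults: 292 accessions, 7,642 SNPs on 7 chromosomes of
600 Mb, allele frequencies uniform on [0.05, 0.5], 4 environments, 5 QTL at
5% of variance each, cross-environment effect correlation 0.5, polygenic
h² = 0.5, 5% missing genotypes, 10% missing phenotype cells. Sites are
Hardy–Weinberg and linkage-free: the meta statistic does not require LD and
independent sites keep calibration properties exact. Genotype and
phenotype random streams are decoupled (phenotypes use seed + 1) so
regenerating one does not perturb the other.

Per environment, y = μ_e + Σ_q x_q β_{q,e} + g_e + ε_e with unit target
variance. QTL effect vectors across environments are multivariate normal
with equicorrelation ρ; each QTL's vector is then scaled so the *average
over environments* of its explained-variance fraction equals the target —
exact per-environment scaling would destroy the correlation structure,
and the average-form scaling keeps the degenerate ρ = 1 case exactly
proportional across environments. The polygenic background is drawn with
row covariance h²K (K from the true dosages) and its own cross-environment
equicorrelation (`polygenic_correlation`, defaulting to the QTL value);
this shared realisation is the mechanism that correlates null t-values
between contexts. Environment intercepts are standard-normal draws
(location/season shifts). Missingness is completely at random in both
genotypes and phenotype cells.

What the generator does not emulate: linkage disequilibrium and genetic
map structure, population stratification and family structure beyond the
realised GRM, field spatial effects and replicate-level error structure,
dose–response of the herbicides, inbreeding (sites are outbred HWE, so the
heterozygosity QC rule is not meaningful on simulated data and validation
flows bypass it). Passing the validation suite therefore demonstrates
correctness of the statistical machinery under clean conditions, not
robustness to confounding in real field data.

## Validation experiment sizes

The canned experiments use 200 accessions × 2,000 SNPs × 3 contexts for
null calibration and 400 × 2,000 × 4 for QTL detection and h² recovery
(10–20 seeds), sizes at which the binomial/χ² sampling error of each
reported rate is well inside the stated tolerance bands while a full run
stays in the minutes range. With planted QTL inside the kinship's span the
variance ratio estimates total genomic heritability (≈ 0.75 under the
detection design), so the h² = 0.5 recovery check runs on the matched
no-QTL configuration; single-fit ĥ² has sampling error ≈ 0.15 at this
scale, hence recovery is judged on the pooled median over seeds × contexts.

## Known limitations

- Exact per-SNP REML is not implemented; λ is fixed at the null estimate.
- No covariates, PCs, dominance coding, or multi-locus models.
- The Wald reference is the standard normal; at very small n the
  t-distribution correction would matter, but contexts are guarded to
  n ≥ 30.
- V estimation assumes enough SNPs (pair floor 100); with very few markers
  the correlation estimate is noisy and the repair may trigger.
- Effect-size (fixed/random-effects) meta-analysis and heterogeneity
  statistics are out of scope; only the t-combination statistic is
  provided.
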