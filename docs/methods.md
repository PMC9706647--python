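# Methods

## Problem setting

Two chicken types of Asian origin — Game (large, selected historically for
fighting) and Bantam (small, selected for miniature size) — differ
consistently in body-size traits. Given biallelic SNP dosages for ~200 birds
from 9 breeds nested in those 2 types, plus five morphometric traits per
bird (wing length cm, shank length cm, shank thickness mm, keel length cm,
body weight kg), the package localizes genomic regions associated with the
size difference by two routes: a per-SNP association scan that conditions on
breed, and a selection-style scan built from PCA loading contributions.
Because breed is nested in type, the two routes see different signals: the
association scan needs within-breed segregation, while the PCA scan keys on
between-type frequency differentiation. A region found by both is the
strongest class of candidate.

## Data model and conventions

* Dosages count copies of the **dataset-wide minor allele** (0/1/2; missing
  is a distinct NaN sentinel, never 0). After loading, allele orientation is
  recomputed from pooled frequencies; an exact 0.5 tie orients to the
  lexicographically smaller allele. The reported β is therefore always "per
  minor-allele copy".
* Genomic coordinates are 1-based inclusive internally; BED export converts
  to 0-based half-open exactly once, at write time.
* Heterogametic-sex dosage on Z is treated like autosomal dosage throughout
  (females are ZW); this mirrors common array practice for mixed-sex panels
  but slightly misstates female Z dosages — a known limitation.

## Quality control

Three nested marker sets feed the three analysis stages:

1. **Filter cascade** (clustering set): remove markers with call rate
   < 95 %, then markers monomorphic among non-missing calls, then markers
   with MAF < 0.05, in that fixed order. All inequalities are strict, so a
   call rate of exactly 95 %, a MAF of exactly 0.05, and later a genotype
   class of exactly 10 birds are kept. Per-rule removal counts depend on the
   order and are reported for the order run; the survivor set does not.
   Monomorphism is checked in the pooled sample — a marker polymorphic in
   any breed is polymorphic pooled, so the pooled check is equivalent.
2. **Class masking** (association set): any genotype class with fewer than
   10 birds has its entries set missing (guarding the scan against hits
   driven by a handful of animals), then the cascade re-runs.
3. **Complete cases** (PCA set): only markers with zero missing entries,
   since the SVD requires a complete matrix.

MAF from class counts is `(2·n_minor_hom + n_het) / (2·n_total)` with
missing birds excluded.

## Clustering

Pairwise Euclidean distances over dosages use pairwise-complete markers and
rescale by `sqrt(M / M_ij)` (total over shared marker count) so pairs with
different missingness stay comparable; a pair sharing no markers is an
error. Complete-linkage agglomeration (scipy) builds the dendrogram; merge
heights are monotone by construction of the maximum-linkage update. Cutting
at k = number of breeds, a bird whose cluster's majority breed differs from
its own label is flagged as an outlier; clusters with tied majorities are
excluded with a warning. Equal-height merge ties follow scipy's internal
order; on real-valued genotype distances ties have measure zero.

## Phenotype preparation

Sex correction is fitted **per breed × trait** with the one-factor model
`Y = μ + Sex + e`; the corrected value is the fitted intercept plus the
residual, equivalently `Y − own sex-group mean + reference-sex mean`
(reference sex: female, configurable). Single-sex breeds pass through with a
warning. The choice of reference sex shifts each breed by a constant, which
the Breed term of the association model absorbs — association p-values are
invariant to it (tested to 1e-9). Type comparisons per trait × sex use
Student's t with pooled variance (Welch behind a flag), thresholded at
`0.05 / (5 traits × 2 sexes) = 0.005`.

A subtlety of this two-stage recipe: subtracting the within-breed sex-group
mean removes a small amount of genuine marker signal (the group mean of the
marker's own contribution), attenuating downstream effect estimates by a
factor of roughly `1 − 1/n_group` (~5 % at group sizes near 10). This is a
property of the procedure itself, not of its implementation; effect-recovery
checks therefore plant effects directly on the corrected scale.

## Association scan

Per marker and trait, the F-test compares `Y′ = μ + Breed + SNP + e` (SNP as
genotype-class factor, up to 2 df) against `Y′ = μ + Breed + e` on
pairwise-complete observations. β and its SE come from a second fit with the
0/1/2 dosage in place of the factor, honoring the factor-coded test and the
additively-coded effect simultaneously. Variance explained is
`100·(RSS_reduced − RSS_full)/RSS_reduced` from the factor fit. Markers with
one observed class are skipped; markers constant within every breed are
flagged as collinear with the breed term (their p is undefined — the scan
cannot see purely type-differentiated loci, which is exactly the gap the
PCA scan fills).

FDR is Benjamini–Hochberg per trait across all tested markers (statsmodels
step-up; pooling across traits is deliberately not done because results are
reported per trait). When more than 100 markers pass FDR < 0.05, region
building first applies the stricter FDR < 0.01 screen — the treatment given
to marker-dense traits.

λ transforms p-values to 1-df χ² quantiles and divides the observed median
by 0.4549. The alternative literal reading (median p / 0.5) is available
via `literal=True`; the quantile form is the field standard and is the one
whose null expectation is exactly 1.

LD r² between unphased markers is estimated by EM over haplotype
frequencies (initialized at linkage equilibrium, ≤100 iterations or
Δ < 1e-8; the double heterozygote is the only phase-ambiguous class), then
`r² = D²/(p_A p_a p_B p_b)`. Consecutive significant markers on a
chromosome join one region iff r² strictly exceeds 0.5; regions are the
transitive closure of adjacent joins, and "adjacent" means consecutive in
the significant list, not on the array. Top marker: lowest raw p, ties to
the lowest position.

## PCA contribution scan

PCA is the SVD of the column-centered (not scaled — the standard choice for
genotype PCA at moderate MAF; `scale=True` available) complete-case matrix;
component SDs use the n−1 denominator. For the scanned component (1 by
default, since PC1 separates the types): variable correlation =
loading × component SD, cos² = its square, contribution = cos² as a
percentage of the component's total (summing to 100; the SD cancels, so
contribution reduces to 100·loading²).

`pcaDObs = sign(loading) × contribution` (sign(0) counts as +). P-values
refer each |pcaDObs| to Normal(μ̂, σ̂) fitted to the statistic's own vector:
`p = min(1, 2·P[X > |pcaDObs|])`, Bonferroni-adjusted over the M markers in
the PCA set; selection at adjusted p < 0.05. Two numerical choices: the cap
at 1 (the raw formula exceeds 1 whenever |pcaDObs| < μ̂), and evaluating the
normal model with |μ̂| — the SVD fixes orientation only up to sign, and
using the canonical nonnegative-mean orientation makes p-values and the
selected set exactly invariant to that arbitrary sign (the formula is
unchanged whenever μ̂ ≥ 0, and μ̂ is O(1/M) in practice). σ̂ is the sample
SD (n−1); at realistic marker counts the n vs n−1 difference is negligible.

Selected SNPs chain into a region while each sits within 2 Mb of the
previous member (region ends may be farther apart). Top marker: smallest
raw p, ties to largest |pcaDObs|, then lowest position. Component scores
are rank-correlated (Spearman) with the raw traits as a sanity check that
the leading component tracks body size.

## Synthetic panels

The generator emulates the study panel's structure rather than any real
genotypes. Markers are placed uniformly at random along 5 chromosomes
(lengths roughly matching chicken chromosomes 1, 2, 4, 10 and Z) and
sorted. Allele frequencies follow two levels of Balding–Nichols drift:
ancestral p ~ U(0.1, 0.9); type frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F)
with F_type; breed frequency drifts analogously from its type with F_breed;
F = 0 passes frequencies through. Genotypes are Binomial(2, breed
frequency); traits are breed baseline + per-breed sex effect + Σ(additive
effect × dosage) + Gaussian noise; missing calls are dropped uniformly.

Defaults, chosen once: the 9 study breed sizes and sex splits (201 birds;
94 Game, 107 Bantam); **F_type = 0.10**, anchored so the leading PC carries
≈13–14 % of genotypic variance as in the study panel; **F_breed = 0.08**
(breeds clearly resolvable within type); **missing rate 0.002 per call**, so
roughly half of post-QC markers survive the complete-case reduction,
mirroring the study's proportions; type-level trait means (e.g. body weight
3.2 vs 1.1 kg) and residual SDs at realistic magnitudes, with ±5 % breed
jitter and ~10 % male–female shifts.

Planted architecture in the study-shaped config: 20 type-differentiated
loci with counted-allele frequencies 0.9 vs 0.1 (6 clustered in a ~4 Mb
chromosome-4 window, 14 spread genome-wide), and per-trait causal loci with
effects of 0.15–0.9 trait units per allele. Causal loci draw mid-range
frequencies (U(0.25, 0.5)) and skip drift so they segregate within every
breed — without this, drift occasionally fixes a causal allele in several
breeds and the QC cascade removes it, which would test the drift process
rather than the scans. The chromosome-4 window plants the causal locus
*amid* the differentiated cluster rather than making one SNP both: a fully
type-differentiated causal SNP is near-collinear with the breed covariate
and invisible to the GWAS, whereas the flanked design reproduces the
dual-detection phenomenon (association region and PCA region overlapping in
one window) that motivates running both scans.

What the generator does **not** emulate: background LD (markers are
independent given frequencies; LD-merging logic is exercised with
constructed duplicate-column fixtures), genotyping-error structure beyond
uniform missingness, sex-chromosome dosage, selection sweeps or admixture.
Passing recovery tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to real-data
artifacts such as LD-induced region inflation.

## Validation summary

The test suite checks, among others: worked MAF examples against published
genotype-class counts; the 0.005 Bonferroni threshold; BH-FDR, distance,
linkage and interval-overlap implementations against independent brute-force
oracles; null-scan calibration on 50 synthetic panels (p uniform by KS,
mean λ within 1.00 ± 0.05, false-discovery control within binomial slack);
planted-effect recovery within 2 SE in ≥95 % of replicates; ≥80 % of
planted differentiated loci captured by selected PCA regions with ≤5 % null
selection over 20 panels; and exact internal identities (orientation
invariance, contributions summing to 100, the Var% RSS identity,
reference-sex invariance). Simulation sizes in the suite (400–3000 markers)
were chosen to exercise every stage at panel-realistic sample size (201)
while keeping the full suite fast.

## Known limitations

* The association scan conditions on breed as a fixed effect; loci aligned
  with the breed/type structure are partly or wholly absorbed (no
  mixed-model kinship alternative is provided).
* The pcaDObs normal reference is an empirical approximation; contribution
  distributions are heavy-tailed, so the p-values are calibrated only in
  the sense that extreme-tail selection behaves like an outlier test.
* The two-stage sex correction attenuates effect estimates by ~1/n_group.
* Z-chromosome dosages are treated as autosomal.
* Interval overlap requires a user-supplied known-QTL BED; no database
  retrieval is performed.
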