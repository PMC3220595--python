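# Methods

## Pedigree estimators

Kinship is the probability that two alleles, one sampled from each
individual at the same autosomal locus, are identical by descent (IBD)
within the recorded pedigree. It is computed by the tabular method:
individuals are sorted topologically (founders first) and the full
matrix is filled row by row with Φ(x, x) = ½(1 + Φ(sire, dam)) and
Φ(x, y) = ½[Φ(sire_x, y) + Φ(dam_x, y)] for y earlier in the order.
An unrecorded parent contributes zero, which encodes the model
assumption that founders are non-inbred and mutually unrelated; all
coefficients are therefore relative to the founder population. The
iteration is non-recursive by construction, so pedigrees of arbitrary
depth (tested to 60 generations) cannot overflow the call stack.
Inbreeding is F(x) = Φ(sire_x, dam_x), zero whenever either parent is
unrecorded.

Parent identifiers that never appear as individuals are promoted to
founder records with a warning (herd books routinely cite unregistered
animals); a strict mode turns this into an error. Cycles are rejected
with the offending chain named.

### Pedigree completeness

The completeness index over d ancestral generations (d = 5 by default;
generation 1 = parents) counts, separately for the paternal and
maternal lines, the proportion gᵢ of known ancestors in generation i
relative to the full generation size 2ⁱ — so a completely recorded
line contributes C = (1/d)·Σ gᵢ = ½ — and combines the lines as

    PEC = 4·C_sire·C_dam / (C_sire + C_dam).

A fully recorded pedigree gives PEC = 1; an individual with even one
unrecorded parent gets PEC = 0, a surprising but formula-forced
consequence of the harmonic-style combination (an entirely unknown
line cannot be compensated by the other). An ancestor appearing twice
fills two slots; multiplicity is intentional, since the index measures
record depth, not distinct-ancestor counts. Deleting a recorded link
can only remove filled slots, so PEC is monotone under record loss
(property-tested).

## Genomic estimators

Genotypes are held as an individuals × loci minor-allele dosage matrix
(0/1/2, −1 missing). Only autosomal, polymorphic loci enter
estimation; pairwise statistics use pairwise-complete loci and
per-individual statistics the individual's non-missing loci — no
imputation anywhere.

**Inbreeding (method of moments).** For an individual with L observed
loci, F = (O(Hom) − E(Hom)) / (L − E(Hom)), with per-locus expected
homozygosity 1 − 2pq·2n/(2n−1). The 2n/(2n−1) factor corrects the
expectation for estimating p from the same finite sample; a flag
disables it. Negative estimates are sampling error around F = 0 and
are kept in the `F_raw` column; the reporting column `F` truncates at
zero. The reference frequencies default to the whole cohort
("homogeneous population"); passing within-subpopulation frequencies
gives the stratified variant. The homogeneous variant is inflated in
a substructured cohort (a Wahlund-type effect); the per-subpopulation
mean of that inflation is what `stratified_bias` reports, and in the
simulated cohort it is largest for the smallest, and in the real-world
analogue most isolated, subpopulation.

**Robust kinship.** The pairwise estimator uses only the two genotype
vectors — heterozygote counts N_Aa⁽ⁱ⁾, N_Aa⁽ʲ⁾, the joint-heterozygote
count N_Aa,Aa and the opposite-homozygote count N_AA,aa:

    φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (2·min(N_Aa⁽ⁱ⁾, N_Aa⁽ʲ⁾))
         + ½ − (N_Aa⁽ⁱ⁾ + N_Aa⁽ʲ⁾) / (4·min(N_Aa⁽ⁱ⁾, N_Aa⁽ʲ⁾)).

No allele frequency enters, so the estimate is invariant to which
other samples are genotyped and to allele orientation (both
property-tested); duplicate samples give exactly ½. Pairs with fewer
than 100 pairwise-complete loci (configurable) or no heterozygous
calls in one member are reported missing, never zero. The
zero-IBD-sharing probability is π̂₀ = N_AA,aa / Σ 2p²q², clamped to
[0, 1]: only pairs sharing zero alleles IBD can show opposite
homozygotes, and the denominator is that count's expectation for a
fully unrelated pair. Parent–offspring pairs give π̂₀ = 0 exactly
(Mendelian constraint).

**Degree classification.** Kinship cutoffs at 2^(−3/2), 2^(−5/2),
2^(−7/2), 2^(−9/2) (upper bounds inclusive) separate duplicate/MZ,
1st-, 2nd-, 3rd-degree and unrelated pairs; these are the geometric
midpoints between the theoretical class values ½, ¼, ⅛, 1/16, 0.
Within first degree, π₀ < 0.1 labels a pair parent–offspring
(theoretical π₀ = 0) rather than full-sib (π₀ ≈ ¼); 0.1 sits well
below the full-sib expectation while tolerating genotyping noise.

**Filters.** LD pruning slides a 50-SNP window in steps of 5 within
each chromosome and greedily removes one member (lower MAF; tie → the
later position) of any retained pair with dosage r² > 0.5. The
Hardy–Weinberg filter uses the exact conditional test (enumeration of
the heterozygote-count distribution given allele counts) at
α = 0.01; a chi-square alternative sits behind a flag. Because the
conditional distribution is discrete the exact test is conservative:
under a simulated null its rejection rate is below the nominal 1%, and
the calibration test asserts exactly that (non-zero, never above the
binomial upper bound at α) rather than a two-sided band around 1%.

## Structure

The IBS distance D = 1 − (IBS2 + ½·IBS1)/N is computed over
pairwise-complete loci. Classical (Torgerson) scaling double-centers
−½·J·D²·J and uses the top-k positive eigenvalues; negative
eigenvalues (non-Euclidean D) are dropped, not truncated into
coordinates, and an all-zero geometry raises unless the caller opts
into a zero configuration. Axis signs are arbitrary; tests compare
configurations only up to Procrustes alignment.

FST is the Weir–Cockerham θ estimated from per-locus variance
components a (among populations), b, c, combined across loci as
Σa / Σ(a+b+c) (ratio of sums, the standard multi-locus combination for
this estimator family — not the mean of per-locus ratios, which is
biased at low-information loci). Loci where the components are
undefined (monomorphic-in-sample, a subpopulation unrepresented) are
skipped. The within-subpopulation share of variation is reported as
1 − θ̂. Significance comes from permuting individual labels with the
add-one estimator p = (1 + #{θ_perm ≥ θ_obs}) / (n_perm + 1), which
cannot return zero and is uniform under the null up to the 1/(n+1)
lattice (calibration-tested by Kolmogorov–Smirnov over replicate null
cohorts).

## Synthetic cohorts

The generator emulates a small substructured herd-book population:

* **Shape.** Three subpopulations of 54/31/14 genotyped individuals —
  the sizes of the coat-colour groups in the motivating sheep cohort —
  and 5000 unlinked autosomal SNPs by default (the array-scale 47 693
  is a parameter). Ancestral pool frequencies are Uniform(0.05, 0.95)
  per locus.
* **Differentiation.** Default: 11 generations of binomial drift at
  subpopulation size N = 100, giving expected
  FST = 1 − (1 − 1/2N)¹¹ ≈ 0.054, the level reported for the
  motivating population; a Balding–Nichols draw with θ = 0.054 is the
  alternative model. Loci that fix are redrawn (rejection), never
  clamped, so monomorphic subpopulation frequencies cannot occur.
* **Pedigree design.** Relationship motifs built from fresh unrelated
  founders: full-sib, half-sib, avuncular, first-cousin and
  parent–offspring pairs, plus cousin-, half-sib- and full-sib-mating
  loops (designed F = 1/16, 1/8, 1/4) and 18 individuals with fully
  recorded 5-generation ancestries. Designed truth (pair Φ and
  individual F) is recorded before any record degradation and is
  cross-checked against the recursive engine in tests.
* **Record incompleteness.** Recording quality clusters by lineage,
  as it does in real herd books: each sampled individual is poorly
  recorded with its subpopulation's rate (0.1/0.2/0.5, poorest in the
  smallest "grey" analogue), and ancestor records reached only through
  poorly recorded animals lose each parent link with probability ½.
  This reproduces a completeness spread from 0 to 1 with a complete-
  pedigree subset, rather than the uniformly-shallow pedigrees that
  per-link deletion would produce.
* **Gene dropping.** Founders receive two uniquely labelled alleles
  per locus (state Bernoulli(p) of their subpopulation); non-founders
  inherit one uniformly random allele per parent, independently per
  locus. Labels are retained, so realized IBD sharing is auditable
  exactly, and the gene-drop estimate serves as the independent
  Monte-Carlo oracle for the recursive kinship engine (each unlinked
  locus is an independent segregation replicate).

What the generator does **not** model: linkage and recombination (loci
are exchangeable and independent; an optional correlated-column mode
only exercises the LD pruner), genotyping error, call-rate structure
(missingness is uniform), selection, assortative mating, and
overlapping generations. Tests passing on these cohorts therefore
validate estimator correctness under the stated model, not robustness
to array artefacts or linkage disequilibrium in real panels.

## Comparison of the two arms

F_SNP is regressed on F_PED by ordinary least squares with R² the
squared Pearson correlation; raw (untruncated) estimates enter by
default since truncation at zero would distort the regression, with a
flag for the truncated variant. Degree agreement is a 5×5
cross-tabulation over the fixed category order; per-degree agreement
is summarized as mean ± SD of |Φ_PED − Φ_SNP|. Threshold proportions
use strict inequality against the first-cousin-mating level
F = 0.0625. On the simulated cohort with its complete pedigree both
arms estimate the same truth, and the regression recovers slope ≈ 1,
R² > 0.8 at 5000 loci; with the degraded (as-recorded) pedigree the
slope and R² drop — the same mechanism that limits agreement in real
herd-book comparisons.

## Problem sizes and numerical choices

Default test and analysis runs use 99 individuals and 2000–5000 loci;
recovery checks that need tighter Monte-Carlo error use 10 000–20 000
loci (200 full-sib pairs for kinship recovery; 3 × 33 Hardy–Weinberg
individuals at 20 000 loci for FST recovery), sizes at which the
binomial sampling error of each check sits well inside its stated
tolerance. Pairwise statistics are computed by dense 0/1 matrix
products (counts are exact in float32 below 2²⁴; ratio arithmetic is
done in float64). PSD of relationship matrices is asserted to 1e-8.
All randomness flows from explicit seeds; identical seeds give
byte-identical fixtures.
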