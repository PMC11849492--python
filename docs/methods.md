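# Methods

This note documents the models, the synthetic cohort generator, the numerical
conventions, and the design choices behind `dermalink`, in the spirit of the
methods documentation of simulation and statistics packages.

## Statistical primitives (`dermalink.stats`)

**Spearman correlation.** rho is the Pearson correlation of midranks; the
two-sided p-value uses the t statistic t = rho·sqrt((n−2)/(1−rho²)) with n−2
degrees of freedom. Constant inputs raise ("zero rank variance") rather than
returning NaN, because every downstream use treats a constant feature as a
data error or a filter target.

**Age-adjusted (partial) Spearman.** All three vectors are midrank
transformed; the first-order partial Pearson correlation of the ranks
controls the covariate, with n−3 degrees of freedom for the p-value. The
adjustment method is a design choice: stratification was the alternative,
but partial correlation on ranks is deterministic, needs no binning choice,
and reduces exactly to the plain Spearman correlation when the covariate is
rank-orthogonal to both variables. Exact rank collinearity between the
covariate and either variable leaves the partial correlation undefined
(0/0) and raises; callers that can encounter it (e.g. a diversity measure
constructed to be exactly monotone in age) should add noise or use the
unadjusted mode.

**Mann–Whitney U.** U is derived from midrank sums. For pooled samples of at
most 16 observations without ties the p-value is exact: the null
distribution of U is built from the recurrence N(u; n₁, n₂) =
N(u−n₂; n₁−1, n₂) + N(u; n₁, n₂−1) and the two-sided p is the symmetric
tail mass P(|U − n₁n₂/2| ≥ |u − n₁n₂/2|). Otherwise a normal approximation
with tie correction and a 0.5 continuity correction is used. The exact
branch is limited to tie-free small samples because the module enrichment
test compares hundreds of correlation values where exactness is infeasible
and unnecessary; the two branches agree within |Δp| ≤ 0.02 at n₁ = n₂ = 8
(tested).

**FDR.** Benjamini–Hochberg step-up q-values throughout, cross-checked
against a brute-force implementation of the step-up definition.

**75th percentile.** Linear interpolation at h = (n−1)·0.75. The convention
is fixed (and identical between the canopy iteration and the final CAG
profile) so co-abundance group profiles are bit-reproducible.

## Synthetic cohort generator (`dermalink.simulate`)

The generator emulates the joint structure of a cheek-metagenome /
skin-imaging cohort of adults aged 20–60. Defaults: 150 samples, 40
species, 90–130 genes per species (~4400 genes), 300 KOs of which 20
modules of 8 KOs each occupy a prefix, three target modules owned by the
driver species, and an annotation layer at 98 ± 1.5 % identity with 5 % of
genes unannotated.

**Phenome.** Each SIP is affine in age and gender plus Gaussian noise,
truncated at zero (device scores are non-negative):
SIP = a + b·age + c·[male] + sd·ε. The default slopes follow the known
qualitative age directions (pigment, pore, UV spot, melanin, hemoglobin and
wrinkle rise; lightening and texture decline; sebum and porphyrins are
flat), with noise chosen so the age correlations are detectable but not
trivial (|r| ≈ 0.3–0.45).

**Species.** Species s has a base log-loading m_s ~ Normal(0, 1.2), sorted
descending so one taxon dominates the community the way a sebaceous-skin
community is dominated by a single species. Sample-level logits are
m_s / (1 + λ·age_norm) + 0.8·z with λ = `diversity_age_effect` (default
0.5) and age_norm ∈ [0, 1]; softmax normalization yields relative
abundances. Flattening the loadings with age makes Shannon diversity rise
with age, matching the repeatedly observed age trend of skin microbiota.

**Driver coupling.** The target SIP's noise and the driver species' logit
noise share a Gaussian latent u with mixing weight w:
ε = w·u + √(1−w²)·e. Because softmax normalization, age trends, and gene
noise all attenuate the realized rank correlation, w is calibrated by
binary search against the empirical Spearman correlation of the full
generative mechanism at n = 4000. The achieved correlation and w are
recorded in the truth record.

**Genes.** Gene g of species s has abundance A_s · b_g · exp(σ·z) with
baseline b_g log-uniform over two orders of magnitude and σ =
`within_species_log_noise_sd` = 0.1. Because the shared species factor
A_s varies over orders of magnitude across samples while the gene noise is
small, within-species gene pairs have Pearson r > 0.9 essentially always
(tested at ≥ 99 % of pairs), which is what makes canopy clustering
recover species-of-origin.

**KO/module assignment.** Each KO carries three genes. Target-module KOs
draw their genes from the driver species except that two KOs per target
module keep one non-driver gene — the driver then owns ≥ 90 % of the
module's genes (91.7 % at defaults) while the module still has measurable
KOs after the driver is removed, so the leave-one-out delta is defined.
All other KOs draw three genes uniformly from the remaining pool.

**What the generator does not emulate.** Read-level noise, compositional
zero-inflation, strain variation, co-occurring confounders (season, cosmetic
use), non-linear phenotype trajectories, or overlapping module membership.
Passing tests therefore demonstrate that the pipeline recovers effects of
the planted functional form at realistic effect sizes — not that it is
robust to every failure mode of real skin metagenomes.

## Phenome dynamics

The age regression follows the convention that the SIP is the independent
variable and age the dependent one, so slopes are in years per score unit;
an inverse mode is a one-line change for callers that prefer score-per-year.
Gender is not a covariate in this regression (sign recovery is tested within
gender strata). PCA is computed on z-scored SIP columns (correlation-matrix
PCA) because the ten device scores have heterogeneous units; component signs
are fixed so each loading vector's largest-magnitude entry is positive.

## Age indices

Random forests (scikit-learn, 500 trees, library-default feature
subsampling) inside a seeded 5-fold cross-validation; the out-of-fold
prediction is the sample's skin age. R² is reported per held-out fold and
summarized as mean ± sd; MAE over all out-of-fold predictions. Feature
importance is permutation importance evaluated on the held-out fold (5
repeats) and averaged over folds. Cross-group transfer trains the 5-fold
models on one stratum and averages their predictions on the other. The
integrated feature table concatenates z-scored SIPs with raw species
relative abundances; species features are deliberately untransformed.

## Diversity and PERMANOVA

Shannon and Bray–Curtis operate on per-sample renormalized relative
abundances at species or KO level. PERMANOVA uses the McArdle–Anderson
trace formulation; the p-value permutes the variable's sample labels with a
seeded generator, and an exhaustive mode enumerates all n! relabelings for
n ≤ 7 (used for closed-form fixtures). Per-variable R² values are marginal
(one-variable) fits — order-invariant, unlike sequential sums of squares —
and the joint fit over all SIPs + age gives the combined variance
explained; both are reported. The per-species association model is a
documented linear-model stand-in for MaAsLin-type analyses:
arcsine-square-root transformed relative abundance regressed on the
z-scored SIP and z-scored age, 10 % prevalence filter, BH FDR over all
species × SIP tests.

## CAG/MGS construction

The canopy variant here is deliberately deterministic: seeds are visited in
descending total-abundance order; membership (Pearson r > 0.9 against the
canopy profile) and the 75th-percentile profile are iterated to a fixed
point (≤ 10 rounds); members are then assigned and never revisited; no
canopy merging. Reference canopy implementations leave seed order, merge
rules and the internal profile statistic unspecified, and reproducibility
was judged more valuable than fidelity to an undocumented binary. The gene
count threshold for MGS status is strict (> 500 genes at the cohort scale
this mirrors); on desk-scale synthetic data with ~110 genes per species the
preset is 50. Taxonomy rules count unannotated genes in every denominator,
at all ranks; the identity cutoff inside the 80 % classified-species rule
follows the species-level 95 % convention (the natural reading, flagged as
an open choice); label ties break by supporting gene count, then
lexicographically.

## Module enrichment and driver attribution

KO abundance is the per-sample sum of member-gene abundances (a gene maps
to at most one KO; violations raise). The module test compares in-module KO
SCCs against all out-of-module KO SCCs per SIP (two-sided Mann–Whitney),
with BH FDR computed jointly across all module × SIP pairs — the more
conservative of the per-SIP/global alternatives — at a default threshold of
0.05; min_kos = 3 because a rank test on fewer values is uninformative.
Note that KO SCCs within a species-coherent module are strongly correlated
(they share the species' abundance trajectory), so module-level false
positives concentrate in such modules under the null; the overall null rate
stays near the nominal level (measured ≤ 0.07 over 200 null cohorts).

Leave-one-MGS-out recomputes the module's KO abundances without the
candidate MGS's genes and takes the new median KO SCC; KOs whose abundance
becomes all-zero or constant are dropped from the median (a constant column
has no defined rank correlation) and reported via `n_kos_retained`. The
candidate set defaults to MGSs contributing ≥ 1 gene to ≥ 1 module KO,
since any other MGS provably has delta = 0; iterating all MGSs is available
via the `candidate_mgs` argument. Ranking uses |delta|; the signed delta is
always reported.

## Problem sizes and seeds

The recovery analyses run 20 independent cohorts at the default condition
(150 samples, 40 species, ~4400 genes, 300 KOs, 20 modules, planted
|SCC| = 0.4); null calibration uses 200 smaller cohorts (100 samples, 20
species, 150 KOs, 15 modules) with no planted correlation; PERMANOVA null
rates use 200 replicates of 60 samples at 299 permutations per replicate,
while single PERMANOVA fits default to 9999 permutations. These sizes were
chosen as the smallest at which the planted effects are comfortably
identifiable and the null rates estimable. All randomness flows from
explicit integer seeds (numpy `default_rng`); identical configurations
produce byte-identical outputs, which the pipeline verifies by hashing every
artifact into its manifest.

## Known limitations

- The MaAsLin stand-in is a fixed linear model, not the full MaAsLin
  feature set (no TSS/CLR options, no random effects).
- The canopy variant does not merge canopies; fragmented species would
  appear as multiple CAGs rather than one.
- The module test treats KOs as exchangeable units; it has elevated
  false-positive propensity for modules whose KOs all live in one taxon
  (see above), which is intrinsic to the statistic rather than this
  implementation.
- PERMANOVA supports one categorical or any number of numeric variables;
  interactions and strata are out of scope.
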