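# Methods

`halfsibgs` implements a genomic-selection analysis pipeline for
open-pollinated (maternal half-sib) progeny trials planted across several
sites and genotyped by sequencing (GBS). This note documents the models, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The data model

A trial consists of `f` open-pollinated families planted on `s` sites in
randomized complete blocks. Each tree grows on exactly one site and is
measured once per trait. Genotypes are biallelic SNPs in additive coding
(−1, 0, +1 for aa, Aa, AA; ALT dosage minus one) with `nan` for missing GBS
calls. All statistics downstream of imputation require a complete matrix.

## Synthetic trials (`datagen`)

The generator gene-drops genotypes through an idealized half-sib pedigree:
one mother per family drawn from Hardy–Weinberg proportions at an ancestral
allele frequency sampled uniformly from `maf_range`, one random maternal
allele per offspring locus, and a pollen allele drawn from an unrelated,
non-inbred pollen pool at the ancestral frequency. Expected additive
relationship within a family is therefore exactly 0.25, matching the
assumption of the pedigree model. `fullsib_fraction` optionally sires that
share of each family's offspring by a single hidden father; a fraction `q`
of offspring makes `q²` of within-family pairs full-sib, which is the lever
used to study pedigree-model inflation.

Phenotypes follow `y = site + block(site) + g + e`. Genotype-by-environment
interaction is built in at the QTL level: each site receives its own vector
of QTL effects, drawn jointly with an equicorrelated across-site correlation
equal to `type_b_target`, so the across-site additive genetic (type-b)
correlation is known by construction. The residual variance is calibrated
from the *realized* within-site genetic variance so that single-site
narrow-sense heritability equals `h2_target` in expectation. Five primary
traits (HT, DBH, V_Dir, WD_Res, WD_X-ray) share the QTL set with a preset
genetic correlation matrix in which growth and wood density are antagonistic
(−0.4), the classic wood-quality trade-off; VOL is derived as a smooth
function of DBH²·HT and the dynamic modulus of elasticity as
density × velocity².

Defaults are the "paper-like" preset: 25 families × 3 sites × 10 trees
(750 trees, family size 30), 4 blocks per site, 5 000 SNPs with MAF ∈
[0.05, 0.5], 300 QTL, h² = 0.25, type-b = 0.7, 30 % missingness. GBS
missingness is heterogeneous per SNP (Beta-distributed rates renormalized so
the overall fraction stays within ±1 % of the target).

What the generator does **not** emulate: linkage disequilibrium,
recombination maps, read-level sequencing error, selfing or inbreeding, and
unbalanced family sizes (available only via configuration). Because there is
no LD, imputation and genomic prediction work through family co-segregation
and realized relationships only; masking accuracies (≈0.58–0.64 at 30 %
missing) are therefore lower than values reported for real GBS panels
(≈0.77–0.85), and passing tests demonstrate correct *ordering and
mechanics*, not real-data accuracy levels.

## SNP filtering (`genotypes`)

Filters are applied in a fixed order with disjoint attribution: call rate
(< 0.40 of samples genotyped), missing-data threshold (30 % or 60 %
presets), per-SNP inbreeding coefficient F = 1 − Ho/(2p(1−p)) against a
minimum (the GBS paralog-collapse guard), and minimum MAF (0.05). Two mnF
dialects exist in practice: `min_inbreeding_F = 0.05` (strict; removes
roughly half of HWE-consistent loci along with heterozygote-excess
artifacts) and `−0.05` (lenient; removes only clear excess-heterozygosity
signals). Both are exposed; the pipeline script uses the lenient dialect so
the panel retains most informative SNPs.

## Imputation (`imputation`)

* **MI** — locus-mean fill; the continuous values are retained (MI doubles
  as the initializer of every other method) and a classified variant is
  produced by nearest-centroid assignment to {−1, 0, +1} with ties toward
  the heterozygote.
* **SVD** — iterative truncated-SVD completion (rank default 5, two
  iterations by default); at full rank and enough iterations a low-rank
  matrix's masked cells are recovered exactly.
* **kNN** — marker-wise neighbours: inverse-distance-weighted average over
  the k nearest SNP columns, distances missing-aware and rescaled by the
  pairwise-complete count so sparsity does not shrink them.
* **EM** — probabilistic-PCA column model N(μ, BBᵀ + σ²I) (rank default
  20); per-row conditional expectations via a Woodbury solve, M-step refits
  the factor model from the completed matrix; stops when the largest change
  of any imputed cell is < 0.01 (default, 30 iterations cap). Even without
  LD the *sample* column covariance has rank ≈ families because family
  membership is a hidden row factor, which is exactly the structure the
  model exploits.
* **kNN-Fam** — the family-aware method: for each individual, K1 neighbours
  within its half-sib family ranked by VanRaden genomic similarity (computed
  on the MI-filled matrix) and K2 outside-family neighbours ranked by
  missing-aware Euclidean distance; each missing cell takes the neighbours'
  modal genotype class, ties broken toward the class nearest the locus
  mean. Defaults K1 = 5, K2 = 20. Accuracy rises monotonically with K1 up
  to the family size on synthetic panels, the signature family-information
  effect. `tune_knn_fam` grid-searches (K1, K2) by masking known entries.

Masking evaluation scores exact class recovery at knocked-out cells and
reports per-family accuracies.

## Relationship matrices (`kinship`)

Pedigree A for the half-sib design is 1 on the diagonal, 0.25 within
family, 0 across. The marker matrix is VanRaden's
G = WWᵀ / (2Σp_j(1−p_j)) with observed allele frequencies and columns
centered by 2p_j − 1; monomorphic columns are excluded from both numerator
and denominator. Centering at observed frequencies makes G sum to zero, so
realized within-family values sit slightly below 0.25 with the complement
spread as small negative between-family values; contrasts (within minus
between) recover 0.25 cleanly. Group coancestry Θ is the mean of the
relationship submatrix over all ordered pairs divided by two — the single
place where the relationship scale (self = 1) converts to the coancestry
scale (self = ½). Diversity of a selected set is 0.5/Θ: the status number
N_s under A, founder genome equivalents N_ge under G. A spectral "bending"
helper shifts G when a subset's Θ is non-positive.

## Mixed models (`mixedmodels`)

Multi-site model: `y = site (fixed) + block(site) + a + site×genotype + e`
with `a ~ N(0, K σ²_a)` for K = A or G. The interaction is carried at the
site×family level: with one measurement per tree, a tree-level iid
interaction is confounded with the residual, whereas family×site cells
(≈10 trees each) are estimable — this is the package's resolution of an
ambiguity in how such models are usually written. Single-site model:
`y = mean + block + a + e`; the block term is dropped (with a warning) when
only one level exists.

REML maximizes the restricted log-likelihood directly, by Nelder-Mead over
log-variances (so positivity is built in; boundary solutions appear as
vanishingly small components). Each evaluation costs O(n·q²) after a single
eigendecomposition of K: the genetic term is diagonal in the rotated basis
and the iid design terms (q ≤ ~100 columns) enter through a Woodbury
identity. Standard errors come from the observed information (central finite
differences in variance space); h² standard errors by the delta method.
Heritability is σ²_a/(σ²_a+σ²_sa+σ²_e) multi-site and σ²_a/(σ²_a+σ²_e)
single-site; block variance is excluded, as is conventional.

Because the generator's GxE is individual-level while the fitted interaction
is family-level, the multi-site σ²_sa absorbs only the family-mean share of
interaction variance and multi-site h² estimates sit somewhat below the
single-site calibration target — the same qualitative multi < single pattern
seen in real trials.

## Marker-effect models (`gsmodels`)

RR-BLUP fits `y = 1μ + Zb + e` with Z the VanRaden-centered codes and a
common shrinkage λ = σ²_e/σ²_b estimated by exact REML on the spectrum of
ZZᵀ (one-dimensional profile; no sampling). Solutions use the n-dimensional
dual of Henderson's MME, so cost scales with individuals rather than
markers; on small instances the solution agrees with dense inversion of the
full (1+m) system to machine precision. GEBVs for new individuals are
û + Z_new b̂ with Z_new centered by the *training* frequencies stored in the
model.

GRR re-estimates per-SNP variances σ̂²_bj = b̂_j²/(1 − h_jj) from the
RR-BLUP pass, where h_jj is the marker's leverage in the augmented ridge
system T = [[X, Z], [0, diag(√λ)]], then re-solves with λ_j = σ²_e/σ̂²_bj
(one update by default). The √λ augmentation makes H = T(TᵀT)⁻¹Tᵀ a true
hat matrix with h_jj ∈ [0, 1), which keeps the 1 − h_jj denominator
meaningful; a `literal_diag_lambda` mode augments with diag(λ) instead for
comparison. Degenerate cases are capped: h_jj at 1 − 1e-10 and λ_j at 1e12.
When all σ̂²_bj are equal, GRR reproduces RR-BLUP exactly.

## Cross-validation and type-b correlation (`evaluation`)

Four scenarios: within-site k-fold CV against single-site EBVs; cross-site
(train one full site, validate another, all ordered pairs — replicate
spread from 90 % resampling of the training site, a choice made here because
no replication scheme is standard for that design); pooled multi-site k-fold
CV against multi-site EBVs; and multi-to-single (train pooled, validate each
site against its single-site EBVs; the target site's trees are excluded from
training by default, with a literal train-on-everything variant available).
Accuracy is the Pearson correlation between the concatenated validation
GEBVs of one replicate and the corresponding EBVs. Defaults: 10 folds, 20
replicates.

Validating against EBVs from a single all-data fit follows field practice
but lets validation phenotypes leak into the training response through
co-estimated family means, inflating within-site accuracy relative to
cross-site accuracy even when the across-site genetic correlation is 1
(measured inflation ≈ 0.13–0.19 on synthetic trials). For simulation
benchmarks, `truth_referenced_site_accuracy` refits the single-site mixed
model inside every training fold and scores against the simulator's true
breeding values; under that design within-site and cross-site accuracies
coincide at type-b = 1 as theory requires.

Type-b genetic correlation between two sites treats the trait at each site
as a separate trait and estimates r_B = cov_fam(i,j)/√(var_fam(i)·var_fam(j))
from open-pollinated family statistics: per-site family variance by one-way
ANOVA method of moments, cross-site family covariance from family means
(family-mean noise is independent across sites, so no correction is
needed), clamped to [−1, 1]. The estimator is consistent but ratio-noisy at
small family sizes: at 15 trees/family/site the per-realization sd is
≈ 0.2–0.4 with a small upward (Jensen) bias; at 30 trees/family/site it
recovers simulated targets within ±0.1 on averages over a handful of
trials. Families present at only one site are excluded; at least three
shared families are required.

## Multi-trait composites (`multitrait`)

PCA on standardized EBVs of the five measurement traits
(correlation-matrix PCA, since traits have different units; the derived
VOL and MoE_d are excluded as linear/quadratic functions of the others).
Components are signed so each component's largest-magnitude loading is
positive; only magnitudes and within-component sign patterns are
interpretable. Loading significance is the exact t-test of the trait–score
Pearson correlation. A component's scores can be fed back into the CV
machinery as a composite phenotype. On the synthetic trait set, growth and
wood density oppose each other on PC1 and align on a later component — the
concurrent-selection opportunity such analyses look for.

## Elite selection (`selection`)

Group merit GM(S) = mean BV(S) − c·Θ(S) over subsets of fixed size; the
penalty weight c converts coancestry into breeding-value units. The
optimizer seeds with the top-BV subset (exact at c = 0 and for unrelated
candidates) and applies best-improvement single swaps to a local optimum;
it is deterministic and, on every tested 12-choose-5 instance, matches the
exhaustive oracle (`exhaustive_select`, available up to ~2·10⁶ subsets).
`gain_diversity_curve` sweeps a penalty grid and enforces the frontier
contract by monotone repair: if a larger penalty happens to find higher
gain, the smaller penalty's solution is carried forward. ABLUP selection
pairs pedigree EBVs with A (diversity N_s); GBLUP pairs genomic EBVs with G
(diversity N_ge); since A off-diagonals take only the values {0, 0.25},
N_s moves in coarse steps while N_ge varies continuously.

## Problem sizes in tests and the pipeline script

The test suite and `scripts/acceptance.py` run on synthetic trials sized to
make Monte Carlo error small relative to the tolerances they check:
heritability recovery uses 10 trials of n = 1000; imputation ordering uses
five 1000 × 5000 panels at 30 % missingness; type-b recovery uses 50
families × 30 trees/site × 2 sites averaged over 8 trials; the pipeline
script runs the full default trial (750 × 5000) with 5 CV replicates and
reports replicate standard errors alongside. The exact sizes are stated in
the tests themselves.

## Known limitations

* No LD in the generator: absolute imputation and prediction accuracies are
  not comparable to real GBS data (orderings and contracts are).
* The multi-site interaction is family-level; individual-level GxE variance
  is only partially separated from the residual.
* The type-b estimator is family-mean based and noisy below ~20
  trees/family/site.
* EM imputation convergence (< 0.01 max change) may not be reached within
  the 30-iteration default on large sparse panels; results carry a
  `converged` flag and accuracy is empirically insensitive to the tail
  iterations.
* The pedigree module covers the half-sib design only (no recursive
  pedigrees, dominance, or single-step matrices).
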