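# halfsibgs

Genomic selection toolkit for open-pollinated, multi-site forest-tree
progeny trials genotyped by sequencing (GBS).

Tree breeders evaluating half-sib families across several sites face a
chain of linked problems: GBS genotype tables are 30–60 % missing and must
be filtered and imputed; breeding values and heritabilities are wanted from
pedigree (ABLUP) and marker (GBLUP) mixed models; marker effects must be
fitted and validated within and across sites; several correlated traits need
to be selected on at once; and the final elite set must balance genetic gain
against co-ancestry. `halfsibgs` implements this pipeline end to end,
together with a synthetic-trial generator with known ground truth so that
every stage is verifiable without any external data.

## What is implemented

* **Simulation** (`datagen`) — half-sib multi-site trials: gene-dropped
  genotypes, additive multi-trait phenotypes with site×genotype interaction
  of known type-b correlation, GBS-style heterogeneous missingness, and a
  `TruthRecord` with true breeding values, QTL effects and variance
  components.
* **Genotypes** (`genotypes`) — VCF/TSV I/O in additive (−1, 0, +1)
  coding, allele frequencies, per-SNP inbreeding F, and the GBS filter
  chain (call rate → missing-data threshold → mnF → mnMAF).
* **Imputation** (`imputation`) — mean (MI), iterative truncated SVD,
  marker-wise kNN, low-rank Gaussian EM, and the family-based kNN-Fam
  (K1 within-family neighbours by genomic similarity + K2 outside-family
  neighbours by Euclidean distance, modal-genotype rule), plus masking-based
  accuracy evaluation and (K1, K2) grid tuning.
* **Kinship** (`kinship`) — half-sib pedigree A, VanRaden's
  G = WWᵀ/(2Σp(1−p)), missing-aware individual distances, group coancestry
  Θ and the diversity measures N_s and N_ge = 0.5/Θ.
* **Mixed models** (`mixedmodels`) — REML for the single-site
  (y = μ + block + a + e) and multi-site
  (y = site + block(site) + a + site×genotype + e) individual-tree models
  under A or G; EBVs, variance components with standard errors, and
  narrow-sense h² with delta-method SEs.
* **GS models** (`gsmodels`) — RR-BLUP via Henderson's MME with exact REML
  shrinkage λ = σ²_e/σ²_b, and generalized ridge regression (GRR) with
  SNP-specific λ_j = σ²_e/σ̂²_bj, σ̂²_bj = b̂_j²/(1−h_jj).
* **Evaluation** (`evaluation`) — 10-fold × 20-replicate cross-validation
  in four scenarios (within-site, cross-site, multi-site,
  multi-site→single-site), prediction accuracy as GEBV–EBV correlation, and
  Burdon-style type-b genetic correlations from family (co)variances.
* **Multi-trait** (`multitrait`) — PCA on standardized EBVs and genomic
  prediction of component scores.
* **Selection** (`selection`) — group-merit selection
  GM(S) = mean BV(S) − c·Θ(S) with greedy + swap search, an exhaustive
  oracle for small instances, and gain–diversity frontiers under ABLUP vs
  GBLUP.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import halfsibgs as h

# a 25-family, 3-site trial: 750 trees x 5000 SNPs, 30% missing
cfg = h.SimConfig(seed=1)
ped, geno, masked, mask, pheno, truth = h.simulate_trial(cfg)

filtered, report = h.filter_snps(
    masked, h.FilterSpec(max_missing_fraction=0.60, min_inbreeding_F=-0.05)
)
print(report.n_retained)             # 3911 SNPs kept

imp = h.impute_knn_fam(filtered, K1=5, K2=20)
ev = h.evaluate_imputation(
    geno.subset_snps([geno.snp_ids.index(s) for s in filtered.snp_ids]),
    mask[:, [geno.snp_ids.index(s) for s in filtered.snp_ids]],
    imp.completed,
)
print(round(ev.accuracy, 3))         # 0.585 of masked calls restored exactly

g = h.vanraden_G(imp.completed)
fit = h.fit_multi_site(pheno, ped, g, "HT")
h2, se = h.heritability(fit)
print(round(h2, 3), round(se, 3))    # 0.188 0.077  multi-site GBLUP h2

cv = h.run_scenario(
    "multi_site", {"multi-site": fit.ebv}, imp.completed, ped,
    method="rrblup", trait="HT", k=10, reps=5, seed=1,
)
print(round(cv.mean_accuracy, 3))    # 0.865 GEBV-EBV correlation
```

The imputation accuracy is the fraction of deliberately masked genotype
calls restored to the exact class (synthetic panels carry no linkage
disequilibrium, so this is lower than on real GBS data); the heritability is
the REML estimate of σ²_a/(σ²_a+σ²_sa+σ²_e) under the marker relationship
matrix; the CV accuracy is the correlation between cross-validated genomic
predictions and the multi-site EBVs.

The same pipeline is scriptable from the shell:

```bash
halfsibgs simulate --out trial/ --seed 1
halfsibgs filter trial/genotypes_masked.tsv --out trial/filtered.tsv --max-missing 0.6 --min-f -0.05
halfsibgs impute trial/filtered.tsv --method knn-fam --families trial/pedigree.csv --out trial/imputed.tsv
halfsibgs ebv --phenotypes trial/phenotypes.csv --pedigree trial/pedigree.csv \
          --genotypes trial/imputed.tsv --trait HT --out trial/ebv.csv
halfsibgs cv --scenario multi_site --ebv trial/ebv.csv --genotypes trial/imputed.tsv \
          --pedigree trial/pedigree.csv --trait HT --out trial/cv.csv
```

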