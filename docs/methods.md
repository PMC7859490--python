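# Methods

`panelgp` implements, at desk scale, the standard workflow for improving a
SNP-array genomic prediction panel with sequence variants pre-selected by
GWAS, stratified by functional annotation. This note documents the models,
the synthetic data generator that stands in for field data, the numerical
choices, and what the verification battery does and does not demonstrate.

## Models

**Animal model.** All mixed models are of the single-kernel form
y = Xb + u + e with u ~ N(0, K σg²), e ~ N(0, I σe²), where K is either the
pedigree numerator relationship matrix **A** (expected additive
relationships, tabular method) or a genomic relationship matrix **G**
(VanRaden method 1, G = MM′ / 2Σpⱼ(1−pⱼ) with M the dosage matrix centred
at twice the observed alt-allele frequency). Observed sample frequencies
are used throughout; missing dosages are mean-imputed only inside the GRM
construction, never in QC statistics.

**REML.** Variance components are estimated by profiling the restricted
likelihood down to the single ratio δ = σg²/σe²: K is eigendecomposed once,
every likelihood evaluation is then O(np), and δ is found by bounded scalar
search in log δ over [−6, 6] (`scipy.optimize.minimize_scalar`, xatol
1e−10). σe² is recovered analytically at the optimum as the REML quadratic
form over n − p. Estimates at the search boundary are flagged
(`at_boundary`), not errored; `converged` additionally requires the numeric
derivative of the profile likelihood at the optimum to be below 1e−6. This
derivative-free formulation is exact for the single-kernel model class; we
deliberately avoided AI-REML since no multi-kernel fits are needed.

**Phenotype correction.** Phenotypes are pre-corrected for fixed effects
(sex, contemporary group, centred slaughter-age covariate; reference-level
dummy coding) under the pedigree model: yc = y − X b̂ with b̂ the GLS
solution at the REML optimum using A restricted to the phenotyped animals
(restricting A leaves the marginal model of the phenotyped subset
unchanged). Random effects are intentionally not subtracted — yc retains
the additive-genetic plus residual signal that the downstream GWAS and
GBLUP models consume.

**GBLUP.** With training records yc_t and V = σg² G_tt + σe² I, the overall
mean is the GLS estimate and ĝ = σg² G[:,t] V⁻¹ (yc_t − 1μ̂) for every
animal in G, so validation animals (record-free) receive predictions
through their genomic covariance with the training set. Training-set
predictions coincide with the Henderson mixed-model-equation BLUPs, which
is asserted in the test suite.

**MLMA GWAS.** Per tested SNP, yc = 1μ + s α + g + e with g ~ N(0, G σg²),
where G comes from the same marker region as the tested SNP (no
leave-one-chromosome-out) and the null-model variance components are
estimated once and reused for every marker — the standard two-step
approximation. After one eigendecomposition each marker reduces to a
two-regressor GLS with known weights; α̂²/se² is referred to χ²(1).
Pre-selection takes the k lowest-p markers (ties broken by genomic
coordinate for determinism); hits already on the base panel are retained
there and replaced by the next-ranked candidates so exactly k markers are
added. Composite sets across traits are plain deduplicated unions, with
nominal and actual sizes both recorded.

**Discovery/validation partition.** An animal joins the discovery (GWAS)
cohort iff its largest off-diagonal genomic relationship to any other
animal, on the base-panel GRM, is below 0.30; all others form the
cross-validation cohort. This is the simplest reading of partitioning a
population into animals "without relatives at the threshold"; it guarantees
by construction that no discovery animal has a close relative anywhere,
which is what protects the accuracy evaluation from pre-selection leakage.

**Evaluation.** 10-fold cross-validation with near-equal random folds.
Accuracy = cor(ĝ, yc)/√h²_ref on the validation fold, with h²_ref
estimated once per trait from the base-panel GRM on the full CV cohort, so
every panel is scored against a common denominator; accuracy is not clipped
at 1. Bias is the OLS slope of yc on ĝ (1 = no dispersion bias). Variance
components for each panel's GBLUP are re-estimated once per (trait, panel)
on the full CV cohort and reused across folds; accuracy is the mean of
fold-wise values (per-fold SEs are reported for testability).

## Synthetic populations

The generator reproduces the statistical features the pipeline relies on,
not sequence-level realism.

* **Pedigree.** Founders plus discrete generations under random between-sex
  mating. The sire pool per generation can be restricted (`n_sires`),
  emulating AI usage in beef cattle that creates large paternal half-sib
  families. The default study population (3,400 founders; offspring
  generations of 2,350 and 650 with the second generation sired by 20
  males; cohort = the 3,000 non-founders) was chosen so that the 0.30-GRM
  partition splits the cohort roughly 40/60 into discovery and CV animals,
  the regime in which both a usable GWAS cohort and a predictable CV cohort
  exist. Founders are anchors for the A-matrix but are neither genotyped
  for analysis nor phenotyped.
* **Genotypes.** Founder haplotypes follow a first-order Markov copying
  process: each site either copies the previous site's latent uniform
  (probability ρ, within a chromosome) or refreshes it; the allele is the
  indicator u < pⱼ. Allele frequencies are constant within "LD blocks"
  whose boundaries fall at rate 1 − ρ per site, mirroring the identical
  frequencies of co-segregating alleles in sequence data; within a block
  the adjacent-marker allelic correlation is exactly ρ. Descendants receive
  gametes by Mendelian dropping with crossovers as a Poisson process
  (default 0.01/Mb, i.e. ~1 crossover per 100-Mb chromosome). The default
  ρ = 0.98 makes a large fraction of adjacent sequence-pool pairs exceed
  r² = 0.95, so LD pruning removes a nontrivial share, as it does on real
  sequence panels. Hot loops (founder haplotypes with geometric run-length
  sampling, gamete dropping) are numba kernels; both are exact samplers of
  the stated processes.
* **Marker annotation.** One class per marker ∈ {IGR, ITR, REG, SYN, NSY},
  sampled iid with weights defaulting to genome-survey-like proportions
  (intergenic ≫ intronic ≫ regulatory ≫ coding); composite regions RSN =
  REG ∪ SYN ∪ NSY and WGS = everything. Real annotation classes overlap;
  we force a partition so region-restricted GWAS is unambiguous.
* **Traits.** n_qtl markers sampled (optionally annotation-weighted)
  without replacement; effects normal or gamma-with-random-sign (the gamma
  option gives the few-large-effects architecture of traits like carcass
  weight). TBV = dosage × effect, centred. Residual variance is set from
  the realised TBV variance so TBV/(TBV+e) variance equals the target h²;
  fixed effects (sex ±, contemporary-group N(0, σ_cg), slaughter-age slope)
  are expressed in genetic+residual SD units (defaults 0.3, 0.5, 0.15) and
  the total is rescaled so the population SD matches the trait scale
  (bundled scales: BFT 14.25/5.03 mm, CWT 441.06/52.31 kg, LMA 95.61/12.06
  cm², MS 6.10/1.87). A TruthSet records QTL ids, effects, TBVs, fixed
  effects and the realised h² on the final trait scale.
* **Base panel.** Array-like: markers with MAF ≥ 0.10 picked evenly along
  the genome (commercial chips favour common, well-spaced SNPs); default
  5,000 of the 50,000-marker pool.

What the generator does not emulate: genuine nucleotide context or gene
structure, population-level mutation/drift history (no coalescent),
imputation errors, non-uniform missingness, selection, or
genotype-by-environment effects. Passing tests therefore demonstrate the
pipeline's internal correctness and its qualitative behaviour under a
realistic covariance structure, not field-data effect sizes.

## Quality control

Markers are dropped for MAF < 0.01, call rate < 0.90 or exact-test HWE
p < 1e−6 (the exact conditional test, two-sided by probability mass; the χ²
approximation is anti-conservative near the MAF threshold). Individuals
with more than 10% missing genotypes are dropped. Marker and individual
filters are iterated to a fixed point so QC is idempotent by construction.
LD pruning slides a 100-variant window by 50 variants (half-window);
within a window, each surviving pair closer than 5,000 kb with r² > 0.95
loses one member chosen uniformly at random under the run's seed. r² is
the squared Pearson correlation of dosages over pairwise-complete
observations (unbiased at low missingness; no imputation).

## Numerical choices

* Relationship matrices are float64; the big GRM products may be
  accumulated in float32 (5×10⁻⁸ relative error, irrelevant at three-digit
  reporting) and the REML PSD check tolerates the resulting −1e−4·λmax
  eigenvalue noise. A 1e−6 ridge is applied only inside inversions, never
  stored.
* Ties in p-value ranking break by (chromosome, position); pruning
  victims, fold assignments and all samplers are driven by
  `numpy.random.default_rng` seeds derived from one master seed via
  `SeedSequence([master, crc32(stage)])`, so any stage can be re-run in
  isolation and full runs are byte-identical.
* Degenerate inputs fail loudly: zero-variance phenotypes, rank-deficient
  fixed designs (the confounded columns are named), all-monomorphic
  panels, candidate exhaustion during panel augmentation.

## Verification battery and problem sizes

`scripts/acceptance.py --seed S --out results/acceptance.json` recomputes,
from scratch: exact agreement of the HWE test with an exact-rational
enumeration over every genotype configuration up to 100 observations; the
tabular A-matrix against recursive coancestry on 50 random pedigrees
(≤ ~200 animals); the MME solver against the dense GLS closed form
(n ≤ 50); the REML optimum against a 1,000-point grid; GRM row-sum and
mean-diagonal identities (n = 1,000, m = 10,000); mean REML ĥ² over 20
populations of n = 2,000, m = 5,000 at true h² 0.33 and 0.40; MLMA null
calibration (permuted phenotype, 20,000 markers, n = 800); ten replicates
of the panel-augmentation experiment (3,000-animal cohort, 50,000-marker
pool, 5,000-marker base panel, 100 QTL, h² = 0.33, k = 3,000, 10-fold CV)
reporting base/pre-selected/random accuracies, the relative gain, the
fraction of replicates with positive gain, and the mean bias slope; and
pipeline hygiene (QC idempotence, prune post-condition audit,
discovery/CV disjointness, byte-identical reruns). The GWAS calibration
uses an exchangeable (founders-only) cohort: with family structure, a
single permutation's test statistics all share the realised projection of
the permuted phenotype onto the family axes, so the single-draw KS test
fluctuates even though the long-run size is correct — a property of the
permutation design, not of the estimator.

These sizes were chosen so the whole battery runs on one CPU in well under
half an hour while keeping every Monte-Carlo margin (e.g. ±0.03 on mean ĥ²
over 20 seeds) several standard errors wide.

## Known limitations

* The discovery/CV split depends on the realised GRM noise around true
  relationships; with other marker densities the same pedigree yields
  different cohort sizes.
* Single-trait models only; no dominance, no multi-kernel (e.g. A+G)
  blending, no Bayesian whole-genome regression alternatives.
* MLMA keeps the tested SNP in the GRM; proximal contamination slightly
  deflates power at very high marker-to-QTL LD (the standard trade-off of
  plain MLMA versus LOCO).
* Accuracy can exceed 1 by sampling noise since the h²_ref denominator is
  itself estimated; values are reported unclipped.
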