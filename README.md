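# panelgp

Genomic prediction in livestock routinely runs on a fixed medium-density
SNP array (a "50k chip"), yet imputed whole-genome sequence contains the
causal variants the chip only tags. A widely used remedy is to run a
mixed-linear-model GWAS on a discovery cohort, take the k sequence variants
with the smallest p-values — optionally restricted to a functional
annotation class (intergenic, intronic, regulatory, synonymous,
non-synonymous, or their union) — add them to the array panel, and measure
whether cross-validated GBLUP accuracy improves over the plain array.

`panelgp` implements that entire workflow as a tested Python library plus
CLI, together with a synthetic population generator that reproduces the
statistical structure of field data (multi-generation pedigrees with
paternal half-sib families, LD-structured genotypes, annotation classes,
heritable phenotypes with fixed effects), so every stage is verifiable at
desk scale against ground truth. It is aimed at quantitative-genetics
researchers and students who want a transparent, reproducible reference
implementation of the panel-augmentation strategy.

## The models

All fits are single-kernel linear mixed models

    y = Xb + u + e,    u ~ N(0, K σg²),    e ~ N(0, I σe²)

with K either the pedigree numerator relationship matrix **A** (tabular
method) or VanRaden's genomic relationship matrix
**G** = MM′ / 2Σⱼ pⱼ(1−pⱼ). Variance components come from REML, profiled to
the ratio σg²/σe² after one eigendecomposition of K. On top of this core:

* phenotypes are pre-corrected for fixed effects under the pedigree model
  (yc = y − Xb̂);
* the discovery cohort for GWAS is the set of animals whose maximum
  off-diagonal entry of the base-panel GRM is below 0.30 — animals without
  close relatives — which prevents information leaking from pre-selection
  into the accuracy evaluation;
* per SNP, MLMA fits yc = 1μ + sα + g + e with g ~ N(0, G σg²) and tests
  α̂²/se² against χ²(1), reusing the null variance components;
* prediction accuracy is cor(GEBV, yc)/√h² in validation folds, with h²
  estimated from the base-panel GRM; bias is the regression slope of yc on
  GEBV (1 = unbiased).

## Worked example

```python
import panelgp as pg

params = pg.ScenarioParams(
    n_founders=700, generation_sizes=(500, 200), n_sires=(None, 12),
    n_markers=6000, n_chromosomes=5, base_panel_size=800, n_qtl=50,
    h2=0.33, seed=42,
)
data, truth = pg.simulate_scenario(params)
detail, summary = pg.run_scenario_grid(
    data, regions=("WGS",), k_grid=(500,), n_folds=5, seed=1
)
print(summary.round(3).to_string(index=False))
```

prints

```
trait region   k  mean_accuracy  se_accuracy  mean_bias  se_bias  h2_panel  gain_pct
  CWT   BASE   0          0.717        0.066      0.972    0.119     0.463     0.000
  CWT    WGS 500          0.723        0.063      0.974    0.122     0.476     0.821
  CWT    RAN 500          0.709        0.069      0.970    0.127     0.465    -1.142
```

Reading the rows: on a 700-animal cohort whose carcass-weight-like trait
(true h² = 0.33, realised 0.346) is controlled by 50 QTL, the 800-marker
base panel alone predicts with accuracy 0.717 and dispersion bias 0.972
(≈ 1, i.e. unbiased). Adding the 500 lowest-p GWAS variants from the
6,000-marker sequence pool raises accuracy to 0.723 (+0.8%), while adding
500 random sequence variants does not (−1.1%). At this toy size the gain
sits inside the fold noise (se ≈ 0.06); the full-scale experiment run by
the acceptance script (3,000 animals, 50,000-marker pool, 5,000-marker
base panel, k = 3,000) separates the three panels cleanly, with
double-digit relative gains for pre-selected variants and none for random
ones.

The same workflow is available from the shell:

```bash
panelgp simulate --config config.yaml --out data/
panelgp qc --bfile data/genotypes --prune-r2 0.95 --seed 1 --out data/clean
panelgp pipeline --config config.yaml --out results/
```

Lower-level pieces (`MixedModel`, `GBLUP`, `MLMA`, `build_grm`,
`build_a_matrix`, `correct_phenotypes`, `partition_discovery`,
`augment_panel`, `kfold_split`, …) are importable directly; each fitted
model returns a results object with estimates, uncertainties and a
`summary()`.

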