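"""Cross-validated prediction accuracy and bias over panel configurations.

Accuracy follows the standard animal-breeding definition: the Pearson
correlation between validation GEBVs and corrected phenotypes divided by the
square root of the trait heritability estimated once from the base-panel
GRM on the cross-validation cohort (so panels are compared against a common
denominator). Bias is the ordinary least-squares slope of corrected
phenotypes regressed on GEBV; 1 means no dispersion bias.

:func:`run_scenario_grid` wires the whole experiment: phenotype correction,
base-GRM discovery/CV partition, per-region MLMA on the discovery cohort,
panel augmentation, per-panel REML and k-fold GBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import MLMA
from .kinship import build_grm
from .models import GBLUP, MixedModel, correct_phenotypes
from .selection import (
    augment_panel,
    partition_discovery,
    rank_all,
    random_panel,
)
from .types import GenotypeMatrix, Pedigree, RelationshipMatrix


@dataclass(frozen=True)
class CvDesign:
    """Disjoint near-equal folds over the cross-validation cohort."""

    n_folds: int
    assignment: pd.Series  # animal_id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list:
        return list(self.assignment.index[self.assignment == fold])

    def train_ids(self, fold: int) -> list:
        return list(self.assignment.index[self.assignment != fold])


def kfold_split(cv_ids, n_folds: int = 10, seed: int = 0) -> CvDesign:
    """Random partition into ``n_folds`` folds whose sizes differ by <= 1."""
    ids = list(cv_ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(ids) < n_folds:
        raise ValueError("fewer animals than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    folds[perm] = np.arange(len(ids)) % n_folds
    return CvDesign(
        n_folds=n_folds,
        assignment=pd.Series(folds, index=ids, name="fold"),
        seed=seed,
    )


def prediction_accuracy(gebv_validation, yc_validation, h2_ref: float) -> float:
    """cor(GEBV, yc) / sqrt(h2_ref); unclipped, NaN for zero-variance input."""
    if not (0.0 < h2_ref <= 1.0):
        raise ValueError("h2_ref must lie in (0, 1]")
    g = np.asarray(gebv_validation, dtype=np.float64)
    y = np.asarray(yc_validation, dtype=np.float64)
    if len(g) < 3 or g.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(g, y)[0, 1] / np.sqrt(h2_ref))


def prediction_bias(gebv_validation, yc_validation) -> float:
    """OLS slope of yc on GEBV (1 = dispersion-unbiased)."""
    g = np.asarray(gebv_validation, dtype=np.float64)
    y = np.asarray(yc_validation, dtype=np.float64)
    if g.std() == 0:
        return float("nan")
    return float(np.cov(y, g)[0, 1] / np.var(g, ddof=1))


def evaluate_panel_cv(
    yc: pd.Series,
    G_cv: RelationshipMatrix,
    design: CvDesign,
    h2_ref: float,
    vc=None,
) -> pd.DataFrame:
    """k-fold GBLUP of one panel's GRM: per-fold accuracy and bias.

    Variance components are estimated once on the full CV cohort (unless
    supplied) and reused across folds.
    """
    if vc is None:
        vc = MixedModel(
            yc.loc[list(G_cv.ids)].to_numpy(), np.ones((G_cv.n, 1)), G_cv.values
        ).fit().vc
    rows = []
    for fold in range(design.n_folds):
        val = design.fold_ids(fold)
        train = design.train_ids(fold)
        res = GBLUP(yc.loc[train], G_cv, vc=vc).fit()
        gebv_val = res.gebv(val)
        rows.append(
            {
                "fold": fold,
                "n_validation": len(val),
                "accuracy": prediction_accuracy(gebv_val, yc.loc[val], h2_ref),
                "bias": prediction_bias(gebv_val, yc.loc[val]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["vc"] = vc
    return out


@dataclass
class ScenarioData:
    """Inputs to one scenario run: a post-QC marker pool with phenotypes."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    pedigree: Pedigree
    base_panel_ids: tuple
    traits: list


def run_scenario_grid(
    data: ScenarioData,
    regions: tuple = ("WGS",),
    k_grid: tuple = (1000, 3000, 5000, 10000),
    n_folds: int = 10,
    grm_threshold: float = 0.30,
    seed: int = 0,
    include_random: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full panel-augmentation experiment over trait x region x k.

    Returns (detail, summary): per-fold rows and per-configuration means
    with standard errors and relative accuracy gain over the base panel.
    The base panel appears as region='BASE', k=0.
    """
    geno = data.genotypes
    cohort = list(geno.animal_ids)
    pheno = data.phenotypes.set_index("animal_id").loc[cohort].reset_index()

    base_geno = geno.subset_markers(data.base_panel_ids)
    g_base = build_grm(base_geno)
    discovery, cv = partition_discovery(g_base, grm_threshold)
    if len(cv) < n_folds:
        raise ValueError("cross-validation cohort smaller than fold count")
    design = kfold_split(cv, n_folds=n_folds, seed=seed)
    g_base_cv = g_base.subset(cv)

    detail_rows = []
    meta = {"discovery_ids": discovery, "cv_ids": cv}
    for trait in data.traits:
        corr = correct_phenotypes(pheno, data.pedigree, trait)
        yc = corr.corrected
        yc_cv = yc.loc[cv]

        ref_fit = MixedModel(
            yc_cv.to_numpy(), np.ones((len(cv), 1)), g_base_cv.values
        ).fit()
        h2_ref = ref_fit.vc.h2
        meta[f"h2_ref_{trait}"] = h2_ref

        base_cv = evaluate_panel_cv(yc_cv, g_base_cv, design, h2_ref, vc=ref_fit.vc)
        for r in base_cv.itertuples(index=False):
            detail_rows.append((trait, "BASE", 0, r.fold, r.accuracy, r.bias, h2_ref))

        k_max = max(k_grid) if k_grid else 0
        for region in regions:
            geno_region = geno if region == "WGS" else geno.subset_region(region)
            geno_disc = geno_region.subset_animals(discovery)
            g_region = build_grm(geno_disc, dtype=np.float32)
            scan = MLMA(yc.loc[discovery], geno_disc, g_region).fit()
            ranked = rank_all(scan.table)
            for k in k_grid:
                panel = augment_panel(
                    data.base_panel_ids,
                    ranked,
                    k,
                    provenance={"trait": trait, "region": region, "k": k, "seed": seed},
                )
                fold_df = _panel_cv(
                    geno, panel, cv, yc_cv, design, h2_ref
                )
                for r in fold_df.itertuples(index=False):
                    detail_rows.append(
                        (trait, region, k, r.fold, r.accuracy, r.bias,
                         fold_df.attrs["vc"].h2)
                    )
        if include_random:
            pool = list(geno.marker_ids)
            for k in k_grid:
                panel = random_panel(pool, data.base_panel_ids, k, seed=seed + k)
                fold_df = _panel_cv(geno, panel, cv, yc_cv, design, h2_ref)
                for r in fold_df.itertuples(index=False):
                    detail_rows.append(
                        (trait, "RAN", k, r.fold, r.accuracy, r.bias,
                         fold_df.attrs["vc"].h2)
                    )

    detail = pd.DataFrame(
        detail_rows,
        columns=["trait", "region", "k", "fold", "accuracy", "bias", "h2_panel"],
    )
    detail.attrs.update(meta)
    summary = summarize_grid(detail)
    summary.attrs.update(meta)
    return detail, summary


def _panel_cv(geno, panel, cv, yc_cv, design, h2_ref):
    g_panel = build_grm(geno.subset_markers(panel.all_ids).subset_animals(cv),
                        dtype=np.float32)
    return evaluate_panel_cv(yc_cv, g_panel, design, h2_ref)


def summarize_grid(detail: pd.DataFrame) -> pd.DataFrame:
    """Fold means, SEs and relative gain (%) in accuracy over the base panel."""
    grp = detail.groupby(["trait", "region", "k"], sort=False)
    summary = grp.agg(
        mean_accuracy=("accuracy", "mean"),
        se_accuracy=("accuracy", "sem"),
        mean_bias=("bias", "mean"),
        se_bias=("bias", "sem"),
        h2_panel=("h2_panel", "first"),
    ).reset_index()
    base = summary.loc[summary["region"] == "BASE"].set_index("trait")["mean_accuracy"]
    summary["gain_pct"] = [
        100.0 * (row.mean_accuracy / base[row.trait] - 1.0)
        if row.trait in base.index and base[row.trait] != 0 else np.nan
        for row in summary.itertuples(index=False)
    ]
    return summary


def plot_accuracy(summary: pd.DataFrame, ax=None):
    """Accuracy-by-density panel: one line per region, base as dashed line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for (trait, region), sub in summary.groupby(["trait", "region"]):
        if region == "BASE":
            ax.axhline(sub["mean_accuracy"].iloc[0], ls="--", color="k", lw=1)
            continue
        sub = sub.sort_values("k")
        ax.errorbar(
            sub["k"], sub["mean_accuracy"], yerr=sub["se_accuracy"],
            marker="o", label=f"{trait} {region}",
        )
    ax.set_xlabel("added pre-selected variants")
    ax.set_ylabel("prediction accuracy")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=8)
    return ax
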