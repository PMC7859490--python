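"""Mixed-linear-model association (MLMA) on corrected phenotypes.

Model per tested SNP i:

    yc = 1 mu + s_i alpha_i + g + e,   g ~ N(0, G sigma_g^2)

The polygenic variance components are estimated once under the null
(no SNP) with the region's own GRM and reused for every marker — the
standard two-step MLMA approximation. The tested SNP stays in the GRM
(no leave-one-chromosome-out). After one eigendecomposition of G each
marker costs O(n): the rotated SNP enters a two-regressor GLS with known
weights and alpha_hat^2 / se^2 is referred to chi-square(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import MixedModel, VarianceComponents
from .types import MISSING, GenotypeMatrix, RelationshipMatrix

_CHUNK = 4096


class MLMA:
    """Single-SNP mixed-model GWAS over one marker region.

    Parameters
    ----------
    yc : corrected phenotypes indexed by animal id (discovery animals).
    genotypes : post-QC genotypes of the tested region, same animals.
    G : genomic relationship matrix built from the SAME region's markers.
    vc : optional pre-estimated null variance components.
    """

    def __init__(
        self,
        yc: pd.Series,
        genotypes: GenotypeMatrix,
        G: RelationshipMatrix,
        vc: VarianceComponents | None = None,
    ):
        ids = list(yc.index)
        if list(genotypes.animal_ids) != ids:
            genotypes = genotypes.subset_animals(ids)
        self.genotypes = genotypes
        self.yc = yc.to_numpy(dtype=np.float64)
        self.ids = ids
        self.G = G.subset(ids) if list(G.ids) != ids else G
        self.vc = vc

    def fit(self) -> "GwasResults":
        x0 = np.ones((len(self.ids), 1))
        null = MixedModel(self.yc, x0, self.G.values)
        if self.vc is None:
            self.vc = null.fit().vc
        d, u = null._d, null._u
        w = 1.0 / (self.vc.sigma2_g * d + self.vc.sigma2_e)

        yt = u.T @ self.yc
        ot = u.T @ np.ones(len(self.ids))
        a11 = float(np.sum(w * ot * ot))
        b1 = float(np.sum(w * ot * yt))
        wy = w * yt
        wo = w * ot

        dos = self.genotypes.dosages
        n, m = dos.shape
        obs = dos != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, dos, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = alt / (2.0 * n_obs)
        poly = (n_obs > 0) & (freq > 0) & (freq < 1)

        alpha = np.full(m, np.nan)
        se = np.full(m, np.nan)
        pval = np.full(m, np.nan)
        for lo in range(0, m, _CHUNK):
            hi = min(lo + _CHUNK, m)
            block = dos[:, lo:hi].astype(np.float64)
            miss = ~obs[:, lo:hi]
            if miss.any():
                block[miss] = 0.0
                block += miss * (2.0 * freq[lo:hi])[None, :]
            st = u.T @ block
            a12 = wo @ st
            a22 = (w[:, None] * st * st).sum(axis=0)
            b2 = wy @ st
            det = a11 * a22 - a12 * a12
            ok = poly[lo:hi] & (det > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                a_hat = (a11 * b2 - a12 * b1) / det
                var_a = a11 / det
            alpha[lo:hi] = np.where(ok, a_hat, np.nan)
            se[lo:hi] = np.where(ok, np.sqrt(np.abs(var_a)), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = (alpha / se) ** 2
        pval = stats.chi2.sf(chi2, df=1)
        pval = np.where(np.isnan(chi2), np.nan, np.maximum(pval, np.finfo(float).tiny))

        mk = self.genotypes.markers
        table = pd.DataFrame(
            {
                "marker_id": mk["marker_id"].to_numpy(),
                "chrom": mk["chrom"].to_numpy(),
                "pos_bp": mk["pos_bp"].to_numpy(),
                "freq": freq,
                "alpha_hat": alpha,
                "se": se,
                "p_value": pval,
            }
        )
        skipped = table.loc[~poly, "marker_id"].tolist()
        table = table.loc[poly].reset_index(drop=True)
        return GwasResults(table=table, vc=self.vc, skipped_monomorphic=skipped)


@dataclass
class GwasResults:
    """Per-marker association estimates for one (trait, region) scan."""

    table: pd.DataFrame
    vc: VarianceComponents
    skipped_monomorphic: list = field(default_factory=list)

    def to_gcta_format(self) -> pd.DataFrame:
        """Column layout of the standard MLMA text output."""
        t = self.table
        return pd.DataFrame(
            {
                "Chr": t["chrom"],
                "SNP": t["marker_id"],
                "bp": t["pos_bp"],
                "A1": "alt",
                "A2": "ref",
                "Freq": t["freq"],
                "b": t["alpha_hat"],
                "se": t["se"],
                "p": t["p_value"],
            }
        )

    def summary(self) -> str:
        t = self.table
        lam = float(
            np.median(stats.chi2.isf(t["p_value"], df=1)) / stats.chi2.isf(0.5, df=1)
        ) if len(t) else float("nan")
        return (
            "MLMA scan\n" + "=" * 40
            + f"\nmarkers tested   {len(t)}"
            + f"\nskipped          {len(self.skipped_monomorphic)}"
            + f"\nnull h2          {self.vc.h2:.4f}"
            + f"\nlambda_GC        {lam:.4f}"
            + f"\nmin p            {t['p_value'].min() if len(t) else float('nan'):.3g}"
        )
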