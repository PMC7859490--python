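"""Pedigree (A) and genomic (G) relationship matrices.

A is the numerator relationship matrix from the tabular method; G follows
VanRaden's first method, G = M M' / (2 * sum_j p_j (1 - p_j)), with M the
dosage matrix centred at twice the observed alt-allele frequency.
"""

from __future__ import annotations

import numpy as np

from .types import MISSING, GenotypeMatrix, Pedigree, RelationshipMatrix, UNKNOWN_PARENT


def build_a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    For animal i with parents (s, d) already tabulated:
    a_ii = 1 + a_sd / 2 and a_ij = (a_js + a_jd) / 2 for earlier j;
    an unknown parent contributes 0.
    """
    tab = pedigree.table
    n = len(tab)
    ids = tab["animal_id"].to_numpy(dtype=object)
    index = {a: i for i, a in enumerate(ids)}
    sire = np.array([index.get(s, -1) for s in tab["sire_id"]], dtype=int)
    dam = np.array([index.get(d, -1) for d in tab["dam_id"]], dtype=int)

    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += a[s, :i]
        if d >= 0:
            row += a[d, :i]
        row *= 0.5
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=ids, values=a, kind="PEDIGREE_A")


def build_grm(genotypes: GenotypeMatrix, dtype=np.float64) -> RelationshipMatrix:
    """Genomic relationship matrix (VanRaden method 1).

    Allele frequencies are observed sample frequencies; missing dosages are
    mean-imputed (to 2p_j) only inside this construction. Monomorphic
    markers drop out of both numerator and denominator.
    """
    dos = genotypes.dosages
    obs = dos != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("marker with no observed genotypes; run QC first")
    alt = np.where(obs, dos, 0).sum(axis=0, dtype=np.int64)
    p = alt / (2.0 * n_obs)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic: GRM undefined")
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))

    centred = dos[:, poly].astype(dtype)
    centred[dos[:, poly] == MISSING] = 0.0  # imputed value is 2p, centred to 0
    centred -= np.where(obs[:, poly], 2.0 * p[poly][None, :], 0.0).astype(dtype)
    g = (centred @ centred.T).astype(np.float64) / denom
    g = 0.5 * (g + g.T)
    return RelationshipMatrix(
        ids=genotypes.animal_ids,
        values=g,
        kind="GENOMIC_G",
        meta={
            "freq_source": "observed",
            "n_markers_used": int(poly.sum()),
            "denominator": float(denom),
        },
    )
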