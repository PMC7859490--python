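"""Marker and individual quality control and LD pruning.

Default thresholds follow standard SNP-array practice: markers are dropped
when MAF < 0.01, call rate < 0.90 or the Hardy-Weinberg exact-test p-value
falls below 1e-6; individuals are dropped when more than 10% of their
genotypes are missing. Pruning removes one member (seeded random choice) of
every marker pair with dosage r^2 above 0.95 inside a sliding window of 100
variants capped at a 5,000-kb physical span.

All statistics are computed on observed genotypes only; missing dosages are
never imputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import MISSING, GenotypeMatrix


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test on one marker's genotype counts.

    Conditional on the observed allele counts, the heterozygote count h has
    the distribution P(h) ∝ N! 2^h / (n_AA! h! n_aa!); the p-value is the
    total probability of all h (same parity as the minor-allele count) whose
    probability does not exceed that of the observed h.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        raise ValueError("no observed genotypes")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0  # monomorphic
    hs = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    n_aa = (rare - hs) // 2
    n_bb = n - hs - n_aa
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(hs + 1)
        - gammaln(n_bb + 1)
        + hs * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def marker_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate, MAF and exact HWE p-value from observed calls.

    Markers with zero observations get call_rate 0 and NaN maf/hwe_p
    (undefined flag).
    """
    dos = genotypes.dosages
    n = dos.shape[0]
    obs = dos != MISSING
    n_obs = obs.sum(axis=0)
    n_het = (dos == 1).sum(axis=0)
    n_alt = (dos == 2).sum(axis=0)
    n_ref = (dos == 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2.0 * n_alt + n_het) / (2.0 * n_obs)
    maf = np.minimum(p, 1.0 - p)
    maf[n_obs == 0] = np.nan
    hwe = np.full(genotypes.n_markers, np.nan)
    for j in range(genotypes.n_markers):
        if n_obs[j] > 0:
            hwe[j] = hwe_exact_pvalue(int(n_het[j]), int(n_ref[j]), int(n_alt[j]))
    return pd.DataFrame(
        {
            "marker_id": genotypes.marker_ids,
            "n_obs": n_obs,
            "call_rate": n_obs / n,
            "maf": maf,
            "hwe_p": hwe,
        }
    )


@dataclass
class QcReport:
    """Kept/removed ids with reason codes, mirroring a before/after layout."""

    removed_markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["marker_id", "reason"])
    )
    removed_animals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["animal_id", "reason"])
    )
    n_markers_before: int = 0
    n_markers_after: int = 0
    n_animals_before: int = 0
    n_animals_after: int = 0

    def summary(self) -> pd.DataFrame:
        rows = [
            ("markers", self.n_markers_before, self.n_markers_after),
            ("animals", self.n_animals_before, self.n_animals_after),
        ]
        return pd.DataFrame(rows, columns=["unit", "before", "after"])


def filter_markers(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep markers with maf >= maf_min, call rate >= call_rate_min and
    HWE p >= hwe_p_min; removal reasons follow the first failing criterion
    (MONOMORPHIC before LOW_MAF)."""
    for t in (maf_min, call_rate_min, hwe_p_min):
        if not (0.0 <= t <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
    stats = marker_stats(genotypes)
    maf = stats["maf"].to_numpy()
    cr = stats["call_rate"].to_numpy()
    hwe = stats["hwe_p"].to_numpy()
    with np.errstate(invalid="ignore"):
        maf_ok = (maf >= maf_min) if maf_min > 0 else np.ones_like(cr, dtype=bool)
        cr_ok = cr >= call_rate_min
        hwe_ok = (hwe >= hwe_p_min) if hwe_p_min > 0 else np.ones_like(cr, dtype=bool)
    keep = maf_ok & cr_ok & hwe_ok
    reasons = []
    for j in np.flatnonzero(~keep):
        if not maf_ok[j]:
            reasons.append("MONOMORPHIC" if maf[j] == 0 else "LOW_MAF")
        elif not cr_ok[j]:
            reasons.append("LOW_CALLRATE")
        else:
            reasons.append("HWE_FAIL")
    report = QcReport(
        removed_markers=pd.DataFrame(
            {"marker_id": stats["marker_id"].to_numpy()[~keep], "reason": reasons}
        ),
        n_markers_before=genotypes.n_markers,
        n_markers_after=int(keep.sum()),
        n_animals_before=genotypes.n_animals,
        n_animals_after=genotypes.n_animals,
    )
    out = GenotypeMatrix(
        animal_ids=genotypes.animal_ids,
        markers=genotypes.markers.loc[keep].reset_index(drop=True),
        dosages=genotypes.dosages[:, keep],
    )
    return out, report


def filter_individuals(
    genotypes: GenotypeMatrix, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove animals whose missing-genotype fraction strictly exceeds
    ``max_missing`` (an animal at exactly the threshold is kept)."""
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must lie in [0, 1]")
    if genotypes.n_markers == 0:
        raise ValueError("empty marker panel: nothing to QC")
    miss = (genotypes.dosages == MISSING).mean(axis=1)
    keep = miss <= max_missing
    report = QcReport(
        removed_animals=pd.DataFrame(
            {"animal_id": genotypes.animal_ids[~keep], "reason": "HIGH_MISSING"}
        ),
        n_markers_before=genotypes.n_markers,
        n_markers_after=genotypes.n_markers,
        n_animals_before=genotypes.n_animals,
        n_animals_after=int(keep.sum()),
    )
    out = GenotypeMatrix(
        animal_ids=genotypes.animal_ids[keep],
        markers=genotypes.markers,
        dosages=genotypes.dosages[keep],
    )
    return out, report


def full_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
    max_missing: float = 0.10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Marker filtering followed by individual filtering, iterated to a
    fixed point so that re-running the QC on its own output removes nothing.
    """
    g = genotypes
    removed_m = []
    removed_a = []
    n_m0, n_a0 = g.n_markers, g.n_animals
    while True:
        g, rm = filter_markers(g, maf_min, call_rate_min, hwe_p_min)
        g, ra = filter_individuals(g, max_missing)
        removed_m.append(rm.removed_markers)
        removed_a.append(ra.removed_animals)
        if len(rm.removed_markers) == 0 and len(ra.removed_animals) == 0:
            break
        if g.n_markers == 0:
            raise ValueError("QC removed every marker: empty panel")
    report = QcReport(
        removed_markers=pd.concat(removed_m, ignore_index=True),
        removed_animals=pd.concat(removed_a, ignore_index=True),
        n_markers_before=n_m0,
        n_markers_after=g.n_markers,
        n_animals_before=n_a0,
        n_animals_after=g.n_animals,
    )
    return g, report


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-
    complete observations; NaN when fewer than 3 complete pairs or either
    marker is monomorphic on the complete subset."""
    a = np.asarray(dosages_a, dtype=np.float64)
    b = np.asarray(dosages_b, dtype=np.float64)
    ok = (a != MISSING) & (b != MISSING) & ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return float("nan")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _window_r2(block: np.ndarray) -> np.ndarray:
    """r^2 matrix for a window of dosage columns (animals x markers)."""
    x = block.astype(np.float64)
    x[block == MISSING] = np.nan
    if not np.isnan(x).any():
        sd = x.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x, rowvar=False)
        r[np.isnan(r)] = 0.0
        r[sd == 0, :] = 0.0
        r[:, sd == 0] = 0.0
        return r * r
    m = x.shape[1]
    r2 = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            v = ld_r2(x[:, i], x[:, j])
            r2[i, j] = r2[j, i] = 0.0 if np.isnan(v) else v
    return r2


def _windows(chrom, m, window_variants, step_variants):
    """(start, end) spans of the sliding windows: consecutive markers on one
    chromosome, at most window_variants long, advancing by step_variants."""
    start = 0
    while start < m:
        end = min(start + window_variants, m)
        same = start + int(
            np.searchsorted(chrom[start:end], chrom[start], side="right")
        )
        yield start, min(end, same)
        start += step_variants


def audit_ld_prune(
    genotypes: GenotypeMatrix,
    r2_max: float = 0.95,
    window_variants: int = 100,
    window_kb: float = 5000.0,
    step_variants: int = 50,
) -> int:
    """Count retained within-window pairs exceeding r2_max (brute force).

    Enumerates exactly the windows :func:`ld_prune` visits and recomputes
    every within-span pair's r^2; the result should be 0 on pruned data.
    """
    chrom = genotypes.markers["chrom"].to_numpy()
    pos = genotypes.markers["pos_bp"].to_numpy()
    m = genotypes.n_markers
    violations = 0
    span = window_kb * 1000.0
    for start, end in _windows(chrom, m, window_variants, step_variants):
        for i in range(start, end):
            for j in range(i + 1, end):
                if pos[j] - pos[i] > span:
                    break
                r2 = ld_r2(
                    np.where(genotypes.dosages[:, i] == MISSING, np.nan,
                             genotypes.dosages[:, i]).astype(float),
                    np.where(genotypes.dosages[:, j] == MISSING, np.nan,
                             genotypes.dosages[:, j]).astype(float),
                )
                if not np.isnan(r2) and r2 > r2_max + 1e-12:
                    violations += 1
    return violations


def ld_prune(
    genotypes: GenotypeMatrix,
    r2_max: float = 0.95,
    window_variants: int = 100,
    window_kb: float = 5000.0,
    step_variants: int = 50,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list]:
    """Sliding-window LD pruning.

    A window holds at most ``window_variants`` consecutive same-chromosome
    markers; inside it, every surviving pair that lies within ``window_kb``
    of each other and has r^2 > ``r2_max`` loses one member, chosen
    uniformly at random (seeded), scanning pairs by the left member's
    position. Windows advance by ``step_variants``. Returns the pruned
    genotypes and removed ids.
    """
    if window_variants < 2:
        raise ValueError("window_variants must be >= 2")
    rng = np.random.default_rng(seed)
    chrom = genotypes.markers["chrom"].to_numpy()
    pos = genotypes.markers["pos_bp"].to_numpy()
    m = genotypes.n_markers
    retained = np.ones(m, dtype=bool)

    for start, end in _windows(chrom, m, window_variants, step_variants):
        idx = np.flatnonzero(retained[start:end]) + start
        if len(idx) >= 2:
            r2 = _window_r2(genotypes.dosages[:, idx])
            span = window_kb * 1000.0
            alive = np.ones(len(idx), dtype=bool)
            for i in range(len(idx)):
                if not alive[i]:
                    continue
                for j in range(i + 1, len(idx)):
                    if pos[idx[j]] - pos[idx[i]] > span:
                        break
                    if alive[i] and alive[j] and r2[i, j] > r2_max:
                        victim = i if rng.random() < 0.5 else j
                        alive[victim] = False
                        if victim == i:
                            break
            retained[idx[~alive]] = False

    removed_ids = list(genotypes.marker_ids[~retained])
    out = GenotypeMatrix(
        animal_ids=genotypes.animal_ids,
        markers=genotypes.markers.loc[retained].reset_index(drop=True),
        dosages=genotypes.dosages[:, retained],
    )
    return out, removed_ids
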