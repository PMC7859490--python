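"""Synthetic livestock populations for panel-augmentation experiments.

The generator produces the statistical structure the downstream pipeline
assumes, at desk scale:

* a multi-generation pedigree under random between-sex mating, optionally
  with a restricted sire pool per generation (AI-style polygamy, which is
  what creates large paternal half-sib families in beef cattle data);
* LD-structured diploid genotypes on autosomes: founder haplotypes follow a
  first-order Markov copying process whose adjacent-marker allelic
  correlation is ``founder_ld_rho``, and descendants receive gametes by
  Mendelian dropping with crossovers placed as a Poisson process along the
  physical map;
* functional annotation classes {IGR, ITR, REG, SYN, NSY} sampled per marker
  with genome-survey-like default weights;
* additive trait architectures (QTL count, normal or heavy-tailed gamma
  effect sizes) and phenotypes with sex, contemporary-group and
  slaughter-age fixed effects at a target heritability, reported on a
  chosen mean/SD scale.

Every operation is a pure function of its inputs and an integer seed.
A :class:`~panelgp.types.TruthSet` records QTL positions, effects and true
breeding values so estimators can be scored against the ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .types import (
    ANNOTATION_CLASSES,
    MISSING,
    GenotypeMatrix,
    Pedigree,
    TraitArchitecture,
    TruthSet,
    UNKNOWN_PARENT,
)

#: Default annotation-class weights, proportional to genome-wide variant
#: counts per functional class in cattle sequence data (intergenic and
#: intronic variants dominate; coding classes are rare).
DEFAULT_CLASS_WEIGHTS = {
    "IGR": 9_436_699,
    "ITR": 3_936_080,
    "REG": 968_519,
    "SYN": 59_569,
    "NSY": 27_187,
}

#: Hanwoo-carcass-like trait scales: (mean, SD) in trait units.
TRAIT_SCALES = {
    "BFT": (14.25, 5.03),   # backfat thickness, mm
    "CWT": (441.06, 52.31),  # carcass weight, kg
    "LMA": (95.61, 12.06),  # longissimus muscle area, cm^2
    "MS": (6.10, 1.87),     # marbling score, 1-9
}


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_mating: int = 1,
    seed: int = 0,
    generation_sizes: list[int] | None = None,
    n_sires: int | None = None,
) -> Pedigree:
    """Random-mating pedigree with founders in generation 0.

    Each non-founder generation is produced by matings whose sire is drawn
    (with replacement) from the males of the preceding generation and whose
    dam from its females. By default each generation has
    ``floor(previous/2) * offspring_per_mating`` offspring;
    ``generation_sizes`` overrides the offspring count per generation, and
    ``n_sires`` restricts each generation's sire pool to a random subset of
    that many males (large half-sib families, as under AI).
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if offspring_per_mating < 1:
        raise ValueError("offspring_per_mating must be >= 1")
    if generation_sizes is not None and len(generation_sizes) != n_generations:
        raise ValueError("generation_sizes must have one entry per generation")

    rng = np.random.default_rng(seed)
    records: list[tuple] = []
    # guarantee both sexes among founders by alternating
    sexes = np.array(["M", "F"])[np.arange(n_founders) % 2]
    rng.shuffle(sexes)
    counter = 0
    prev: list[tuple[str, str]] = []  # (id, sex) of previous generation
    for i in range(n_founders):
        aid = f"A{counter:06d}"
        counter += 1
        records.append((aid, UNKNOWN_PARENT, UNKNOWN_PARENT, sexes[i], 0))
        prev.append((aid, sexes[i]))

    for gen in range(1, n_generations + 1):
        males = [a for a, s in prev if s == "M"]
        females = [a for a, s in prev if s == "F"]
        if not males or not females:
            raise ValueError("cannot mate: previous generation lacks one sex")
        if n_sires is not None and n_sires < len(males):
            males = list(rng.choice(males, size=n_sires, replace=False))
        if generation_sizes is not None:
            n_off = generation_sizes[gen - 1]
            n_matings = int(np.ceil(n_off / offspring_per_mating))
        else:
            n_matings = max(1, len(prev) // 2)
            n_off = n_matings * offspring_per_mating
        sires = rng.choice(males, size=n_matings, replace=True)
        dams = rng.choice(females, size=n_matings, replace=True)
        cur: list[tuple[str, str]] = []
        produced = 0
        for mating in range(n_matings):
            for _ in range(offspring_per_mating):
                if produced >= n_off:
                    break
                aid = f"A{counter:06d}"
                counter += 1
                sex = "M" if rng.random() < 0.5 else "F"
                records.append((aid, sires[mating], dams[mating], sex, gen))
                cur.append((aid, sex))
                produced += 1
        prev = cur

    table = pd.DataFrame(
        records, columns=["animal_id", "sire_id", "dam_id", "sex", "generation"]
    )
    return Pedigree(table)


# ---------------------------------------------------------------------------
# marker map & annotation
# ---------------------------------------------------------------------------

def make_marker_map(
    n_markers: int,
    n_chromosomes: int = 10,
    chrom_length_mb: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random marker map: positions uniform on equal-length autosomes."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    rows = []
    bases = np.array(list("ACGT"))
    idx = 0
    for c in range(1, n_chromosomes + 1):
        pos = np.sort(
            rng.choice(int(chrom_length_mb * 1e6), size=per[c - 1], replace=False)
        ) + 1
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((f"M{idx:07d}", c, int(p), bases[ref], bases[alt], "IGR"))
            idx += 1
    return pd.DataFrame(
        rows,
        columns=["marker_id", "chrom", "pos_bp", "ref_allele", "alt_allele", "anno_class"],
    )


def annotate_markers(
    marker_map: pd.DataFrame,
    class_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign one functional class per marker, iid with normalised weights."""
    weights = dict(DEFAULT_CLASS_WEIGHTS if class_weights is None else class_weights)
    unknown = set(weights) - set(ANNOTATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown annotation classes {sorted(unknown)}")
    w = np.array([float(weights.get(c, 0.0)) for c in ANNOTATION_CLASSES])
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("class weights must be non-negative and not all zero")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(ANNOTATION_CLASSES), size=len(marker_map), p=w / w.sum())
    out = marker_map.copy()
    out["anno_class"] = np.array(ANNOTATION_CLASSES, dtype=object)[draws]
    return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@njit(cache=False)
def _founder_kernel(n_haps, p_alt, starts, ends, rho, seed, out):  # pragma: no cover
    np.random.seed(seed)
    log_rho = np.log(rho) if rho > 0.0 else 0.0
    for h in range(n_haps):
        for c in range(starts.size):
            j = starts[c]
            e = ends[c]
            while j < e:
                u = np.random.random()
                if rho > 0.0:
                    r = np.random.random()
                    run = e - j if r <= 0.0 else 1 + int(np.log(r) / log_rho)
                else:
                    run = 1
                stop = min(j + run, e)
                while j < stop:
                    out[h, j] = 1 if u < p_alt[j] else 0
                    j += 1


def _founder_haplotypes(
    n_haps: int, p_alt: np.ndarray, chrom: np.ndarray, rho: float, rng
) -> np.ndarray:
    """First-order Markov haplotypes: each site either copies the previous
    site's latent uniform (probability rho, within a chromosome) or refreshes
    it; the allele is the indicator u < p_alt. For equal adjacent allele
    frequencies this yields adjacent-marker allelic correlation exactly rho.
    Copy-run lengths are sampled geometrically (an exact equivalent of
    per-site Bernoulli refreshing).
    """
    m = len(p_alt)
    starts = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1]]).astype(np.int64)
    ends = np.r_[starts[1:], m].astype(np.int64)
    out = np.empty((n_haps, m), dtype=np.uint8)
    seed = int(rng.integers(2**31))
    _founder_kernel(n_haps, p_alt.astype(np.float64), starts, ends, rho, seed, out)
    return out


@njit(cache=False)
def _gamete_kernel(
    haps, parent_rows, starts, ends, pos_mb, rate, seed, out
):  # pragma: no cover
    np.random.seed(seed)
    for i in range(parent_rows.size):
        p = parent_rows[i]
        for c in range(starts.size):
            s, e = starts[c], ends[c]
            length = pos_mb[e - 1] - pos_mb[s]
            k = np.random.poisson(rate * length) if length > 0 else 0
            phase = 1 if np.random.random() < 0.5 else 0
            if k == 0:
                for j in range(s, e):
                    out[i, j] = haps[p, phase, j]
            else:
                breaks = np.sort(
                    np.random.uniform(pos_mb[s], pos_mb[e - 1], k)
                )
                b = 0
                for j in range(s, e):
                    while b < k and breaks[b] < pos_mb[j]:
                        phase ^= 1
                        b += 1
                    out[i, j] = haps[p, phase, j]


def _gametes_batch(
    haps: np.ndarray,
    parent_rows: np.ndarray,
    chrom_slices,
    pos_mb_full: np.ndarray,
    rate_per_mb: float,
    rng,
) -> np.ndarray:
    """One recombined gamete per parent in ``parent_rows``.

    Crossovers fall as a Poisson process at ``rate_per_mb`` along each
    chromosome; the starting haplotype per chromosome is fair-coin.
    """
    m = haps.shape[2]
    starts = np.array([sl.start for sl in chrom_slices], dtype=np.int64)
    ends = np.array([sl.stop for sl in chrom_slices], dtype=np.int64)
    out = np.empty((len(parent_rows), m), dtype=np.uint8)
    seed = int(rng.integers(2**31))
    _gamete_kernel(
        haps, parent_rows.astype(np.int64), starts, ends,
        pos_mb_full, rate_per_mb, seed, out,
    )
    return out


def simulate_genotypes(
    pedigree: Pedigree,
    marker_map: pd.DataFrame,
    founder_ld_rho: float = 0.6,
    recomb_rate_per_mb: float = 0.01,
    maf_spectrum: tuple = ("uniform", 0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop genotypes through a pedigree over a marker map.

    Founder haplotypes come from the Markov copying process (see
    :func:`_founder_haplotypes`); each non-founder receives one recombined
    gamete from each parent, so dosage = paternal + maternal gamete. An
    optional uniform missingness mask is applied last.
    """
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    if not (0.0 <= founder_ld_rho < 1.0):
        raise ValueError("founder_ld_rho must lie in [0, 1)")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    chrom = marker_map["chrom"].to_numpy()
    pos = marker_map["pos_bp"].to_numpy()
    if not np.all(np.lexsort((pos, chrom)) == np.arange(len(chrom))):
        raise ValueError("marker map must be sorted by (chrom, pos_bp)")

    rng = np.random.default_rng(seed)
    m = len(marker_map)
    tab = pedigree.table
    n = len(tab)

    # Alt-allele frequencies from the MAF spectrum. Frequencies are constant
    # within LD blocks whose boundaries fall with probability (1 - rho) per
    # site (shared across haplotypes): markers in strong LD carry identical
    # frequencies, exactly as co-segregating alleles do in sequence data,
    # and the adjacent-marker allelic correlation within a block is exactly
    # founder_ld_rho.
    kind = maf_spectrum[0]
    if kind == "uniform":
        maf = rng.uniform(maf_spectrum[1], maf_spectrum[2], size=m)
    elif kind == "beta":
        a, b = maf_spectrum[1], maf_spectrum[2]
        maf = 0.5 * rng.beta(a, b, size=m)
    else:
        raise ValueError(f"unknown maf spectrum {kind!r}")
    flip = rng.random(m) < 0.5
    p_alt = np.where(flip, 1.0 - maf, maf)
    new_block = rng.random(m) >= founder_ld_rho
    new_block[np.r_[True, chrom[1:] != chrom[:-1]]] = True
    block_start = np.maximum.accumulate(np.where(new_block, np.arange(m), -1))
    p_alt = p_alt[block_start]

    # chromosome slices & positions in Mb for recombination
    starts = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1]])
    ends = np.r_[starts[1:], m]
    chrom_slices = [slice(s, e) for s, e in zip(starts, ends)]
    pos_mb = pos / 1e6

    haps = np.empty((n, 2, m), dtype=np.uint8)
    index = {a: i for i, a in enumerate(tab["animal_id"])}
    founder_mask = (tab["sire_id"] == UNKNOWN_PARENT) & (tab["dam_id"] == UNKNOWN_PARENT)
    founder_rows = np.flatnonzero(founder_mask.to_numpy())
    # batch founder haplotype generation to bound the float64 scratch arrays
    batch = max(1, int(2e7 // max(m, 1)))
    for lo in range(0, len(founder_rows), batch):
        rows = founder_rows[lo : lo + batch]
        fh = _founder_haplotypes(2 * len(rows), p_alt, chrom, founder_ld_rho, rng)
        haps[rows] = fh.reshape(len(rows), 2, m)

    # drop gametes in waves: a wave is a maximal block of consecutive
    # non-founders whose parents were all tabulated in earlier waves
    nonf = tab.loc[~founder_mask]
    rows_all = np.array([index[a] for a in nonf["animal_id"]], dtype=np.int64)
    sire_rows = np.array(
        [index.get(s, -1) for s in nonf["sire_id"]], dtype=np.int64
    )
    dam_rows = np.array([index.get(d, -1) for d in nonf["dam_id"]], dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    done[founder_rows] = True
    pending = np.arange(len(rows_all))
    while len(pending):
        ready_parent = np.ones(len(pending), dtype=bool)
        for pr in (sire_rows, dam_rows):
            known = pr[pending] >= 0
            ready_parent &= ~known | done[np.where(known, pr[pending], 0)]
        wave = pending[ready_parent]
        if len(wave) == 0:
            raise ValueError("pedigree ordering broken: unresolvable parents")
        for h, pr in enumerate((sire_rows, dam_rows)):
            known = pr[wave] >= 0
            if known.any():
                haps[rows_all[wave[known]], h] = _gametes_batch(
                    haps, pr[wave[known]], chrom_slices, pos_mb,
                    recomb_rate_per_mb, rng,
                )
            if (~known).any():
                # unknown parent: draw fresh founder-style haplotypes
                haps[rows_all[wave[~known]], h] = _founder_haplotypes(
                    int((~known).sum()), p_alt, chrom, founder_ld_rho, rng
                )
        done[rows_all[wave]] = True
        pending = pending[~ready_parent]

    dosages = (haps[:, 0, :].astype(np.int8) + haps[:, 1, :].astype(np.int8))
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = MISSING
    return GenotypeMatrix(
        animal_ids=tab["animal_id"].to_numpy(dtype=object),
        markers=marker_map.reset_index(drop=True),
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# trait architecture
# ---------------------------------------------------------------------------

def simulate_qtl(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    region_enrichment: dict[str, float] | None = None,
    seed: int = 0,
) -> TruthSet:
    """Sample QTL among polymorphic markers and compute true breeding values.

    ``region_enrichment`` gives relative sampling weight per annotation class
    (default: uniform over polymorphic markers). Effects are allele
    substitution effects per alt-allele copy; TBVs are centred.
    """
    rng = np.random.default_rng(seed)
    dos8 = genotypes.dosages
    obs = dos8 != MISSING
    n_obs = obs.sum(axis=0)
    obs_sum = np.where(obs, dos8, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = obs_sum / n_obs
    # polymorphic: at least two distinct observed dosage values
    poly = np.zeros(genotypes.n_markers, dtype=bool)
    for val in (0, 1, 2):
        cnt = ((dos8 == val) & obs).sum(axis=0)
        poly |= (cnt > 0) & (cnt < n_obs)
    n_poly = int(poly.sum())
    if arch.n_qtl > n_poly:
        raise ValueError(f"n_qtl={arch.n_qtl} exceeds {n_poly} polymorphic markers")

    tbv = np.zeros(genotypes.n_animals)
    if arch.n_qtl == 0:
        qtl_ids: list = []
        effects = np.empty(0)
    else:
        weights = np.where(poly, 1.0, 0.0)
        if region_enrichment is not None:
            cls = genotypes.markers["anno_class"].to_numpy()
            wcls = np.array([float(region_enrichment.get(c, 1.0)) for c in cls])
            weights = weights * wcls
        weights = weights / weights.sum()
        qtl_idx = rng.choice(genotypes.n_markers, size=arch.n_qtl, replace=False, p=weights)
        qtl_idx = np.sort(qtl_idx)
        dist = arch.effect_dist
        if dist[0] == "normal":
            effects = rng.normal(0.0, dist[1], size=arch.n_qtl)
        else:  # gamma with random sign
            effects = rng.gamma(dist[1], dist[2], size=arch.n_qtl)
            effects *= rng.choice([-1.0, 1.0], size=arch.n_qtl)
        # mean-impute any masked QTL dosages so truth stays defined
        q = dos8[:, qtl_idx].astype(np.float64)
        masked = ~obs[:, qtl_idx]
        if masked.any():
            q = np.where(masked, col_mean[qtl_idx][None, :], q)
        tbv = q @ effects
        tbv = tbv - tbv.mean()
        qtl_ids = list(genotypes.markers["marker_id"].to_numpy()[qtl_idx])

    return TruthSet(
        qtl_ids=qtl_ids,
        qtl_effects=effects,
        true_breeding_values=pd.Series(tbv, index=list(genotypes.animal_ids)),
    )


def make_fixed_design(
    pedigree_or_ids,
    n_contemporary_groups: int = 20,
    age_mean: float = 30.0,
    age_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotype-table skeleton: sex, contemporary group, slaughter age.

    Sex is taken from the pedigree when one is supplied, otherwise fair-coin.
    Contemporary groups emulate the combined birth/slaughter batch factors of
    field data as one categorical; slaughter age is in months.
    """
    rng = np.random.default_rng(seed)
    if isinstance(pedigree_or_ids, Pedigree):
        ids = pedigree_or_ids.animal_ids
        sex = pedigree_or_ids.table["sex"].to_numpy(dtype=object)
    else:
        ids = list(pedigree_or_ids)
        sex = np.array(["M", "F"])[rng.integers(2, size=len(ids))]
    n = len(ids)
    cg = rng.integers(n_contemporary_groups, size=n)
    age = rng.normal(age_mean, age_sd, size=n)
    return pd.DataFrame(
        {
            "animal_id": ids,
            "sex": sex,
            "contemporary_group": [f"CG{g:02d}" for g in cg],
            "slaughter_age": age,
        }
    )


def simulate_phenotypes(
    truth: TruthSet,
    arch: TraitArchitecture,
    fixed_design: pd.DataFrame,
    seed: int = 0,
    sex_effect: float = 0.3,
    cg_sd: float = 0.5,
    age_slope: float = 0.15,
) -> tuple[pd.DataFrame, TruthSet]:
    """Phenotypes = fixed effects + TBV + residual on the trait's scale.

    The residual variance is set so var(TBV)/(var(TBV)+sigma_e^2) equals the
    target heritability; fixed-effect sizes (``sex_effect``, ``cg_sd``,
    ``age_slope`` per SD of age) are expressed in genetic+residual SD units
    and the total is rescaled so the population phenotypic SD matches
    ``arch.pheno_sd``. The returned TruthSet carries TBVs and fixed effects
    on the final trait scale plus the realised sample heritability.
    """
    if arch.n_qtl > 0 and not (0.0 < arch.target_h2 < 1.0):
        raise ValueError("degenerate residual: target_h2 must be in (0,1)")
    rng = np.random.default_rng(seed)
    ids = list(fixed_design["animal_id"])
    tbv = truth.true_breeding_values.loc[ids].to_numpy()
    v_g = tbv.var()

    if v_g > 0:
        h2 = arch.target_h2
        g_std = tbv * np.sqrt(h2 / v_g)        # genetic part, variance h2
        e_std = rng.normal(0.0, np.sqrt(1.0 - h2), size=len(ids))
    else:
        g_std = np.zeros(len(ids))
        e_std = rng.normal(0.0, 1.0, size=len(ids))

    sex = fixed_design["sex"].to_numpy()
    cg = fixed_design["contemporary_group"].to_numpy()
    age = fixed_design["slaughter_age"].to_numpy()
    age_c = (age - age.mean()) / (age.std() if age.std() > 0 else 1.0)
    levels = pd.unique(cg)
    cg_eff = dict(zip(levels, rng.normal(0.0, cg_sd, size=len(levels))))
    fixed_std = (
        sex_effect * (sex == "M").astype(float)
        + np.array([cg_eff[c] for c in cg])
        + age_slope * age_c
    )
    fixvar = sex_effect**2 * 0.25 + cg_sd**2 + age_slope**2
    scale = arch.pheno_sd / np.sqrt(1.0 + fixvar)

    y = arch.pheno_mean + scale * (fixed_std - fixed_std.mean() + g_std + e_std)

    table = fixed_design.copy()
    table[arch.trait_name] = y
    g_t = scale * g_std
    e_t = scale * e_std
    realized = g_t.var() / (g_t.var() + e_t.var()) if (g_t.var() + e_t.var()) > 0 else 0.0
    factor = scale * np.sqrt(arch.target_h2 / v_g) if v_g > 0 else 0.0
    out_truth = TruthSet(
        qtl_ids=list(truth.qtl_ids),
        qtl_effects=truth.qtl_effects * factor,
        true_breeding_values=pd.Series(g_t, index=ids),
        true_fixed_effects=pd.Series(scale * (fixed_std - fixed_std.mean()), index=ids),
        realized_h2=float(realized),
    )
    return table, out_truth
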