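"""End-to-end synthetic study assembly.

``simulate_scenario`` builds a complete desk-scale analogue of a
SNP-array + sequence-pool genomic-prediction study: a three-tier pedigree
(founders, a broad first generation, a sire-concentrated second generation,
so the cohort mixes weakly related animals with dense paternal families),
LD-structured genotypes, an annotated sequence-like marker pool, an
array-like base panel of common evenly spaced markers, and one phenotyped
trait with known QTL. The defaults are calibrated so that the 0.30
GRM-threshold partition yields roughly a 40/60 discovery/cross-validation
split of a 3,000-animal cohort, mirroring field populations where a minority
of animals lack close genotyped relatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import qc as qc_mod
from .io_formats import stage_seed
from .simulate import (
    TRAIT_SCALES,
    annotate_markers,
    make_fixed_design,
    make_marker_map,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_qtl,
)
from .evaluate import ScenarioData
from .types import GenotypeMatrix, TraitArchitecture, TruthSet


@dataclass
class ScenarioParams:
    """Knobs of the synthetic study; defaults give the desk-scale cohort."""

    n_founders: int = 3400
    generation_sizes: tuple = (2350, 650)
    n_sires: tuple = (None, 20)
    n_markers: int = 50_000
    n_chromosomes: int = 10
    chrom_length_mb: float = 100.0
    founder_ld_rho: float = 0.98
    recomb_rate_per_mb: float = 0.01
    maf_spectrum: tuple = ("uniform", 0.05, 0.5)
    missing_rate: float = 0.0
    base_panel_size: int = 5000
    base_panel_maf_min: float = 0.10
    trait: str = "CWT"
    n_qtl: int = 100
    h2: float = 0.33
    effect_dist: tuple = ("normal", 1.0)
    n_contemporary_groups: int = 20
    run_qc: bool = True
    ld_prune: bool = False
    seed: int = 0


def design_base_panel(
    genotypes: GenotypeMatrix, size: int, maf_min: float = 0.10
) -> tuple:
    """Array-like base panel: common markers picked evenly along the genome.

    Commercial arrays favour common, well-spaced SNPs; we emulate that by
    restricting to markers with MAF >= ``maf_min`` and taking every
    (n_eligible / size)-th one in genomic order.
    """
    from .types import MISSING

    dos = genotypes.dosages
    obs = dos != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, dos, 0).sum(axis=0, dtype=np.int64) / (2.0 * n_obs)
    maf = np.minimum(p, 1.0 - p)
    eligible = np.flatnonzero(maf >= maf_min)
    if len(eligible) < size:
        raise ValueError(
            f"only {len(eligible)} markers with MAF >= {maf_min}, need {size}"
        )
    picks = eligible[np.linspace(0, len(eligible) - 1, size).round().astype(int)]
    return tuple(genotypes.marker_ids[np.unique(picks)])


def simulate_scenario(params: ScenarioParams) -> tuple[ScenarioData, TruthSet]:
    """Simulate a full study and return (data, truth)."""
    p = params
    seed = p.seed

    n_sires = p.n_sires
    if n_sires is not None and not isinstance(n_sires, (list, tuple)):
        n_sires = [n_sires] * len(p.generation_sizes)

    pedigree = _pedigree_with_per_generation_sires(
        p.n_founders, list(p.generation_sizes), n_sires, stage_seed(seed, "pedigree")
    )

    marker_map = make_marker_map(
        p.n_markers, p.n_chromosomes, p.chrom_length_mb, stage_seed(seed, "map")
    )
    marker_map = annotate_markers(marker_map, seed=stage_seed(seed, "annotation"))

    geno_all = simulate_genotypes(
        pedigree,
        marker_map,
        founder_ld_rho=p.founder_ld_rho,
        recomb_rate_per_mb=p.recomb_rate_per_mb,
        maf_spectrum=p.maf_spectrum,
        missing_rate=p.missing_rate,
        seed=stage_seed(seed, "genotypes"),
    )
    cohort = list(
        pedigree.table.loc[pedigree.table["generation"] >= 1, "animal_id"]
    )
    geno = geno_all.subset_animals(cohort)

    if p.run_qc:
        geno, _ = qc_mod.full_qc(geno)
    if p.ld_prune:
        geno, _ = qc_mod.ld_prune(geno, seed=stage_seed(seed, "prune"))

    base_ids = design_base_panel(geno, p.base_panel_size, p.base_panel_maf_min)

    mean, sd = TRAIT_SCALES.get(p.trait, (0.0, 1.0))
    arch = TraitArchitecture(
        trait_name=p.trait,
        n_qtl=p.n_qtl,
        effect_dist=p.effect_dist,
        target_h2=p.h2,
        pheno_mean=mean,
        pheno_sd=sd,
    )
    truth0 = simulate_qtl(geno, arch, seed=stage_seed(seed, "qtl"))
    design = make_fixed_design(
        geno.animal_ids,
        n_contemporary_groups=p.n_contemporary_groups,
        seed=stage_seed(seed, "design"),
    )
    # sex must agree with the pedigree for the correction model
    sex = pedigree.table.set_index("animal_id")["sex"]
    design["sex"] = sex.loc[design["animal_id"]].to_numpy()
    phenotypes, truth = simulate_phenotypes(
        truth0, arch, design, seed=stage_seed(seed, "phenotypes")
    )

    data = ScenarioData(
        genotypes=geno,
        phenotypes=phenotypes,
        pedigree=pedigree,
        base_panel_ids=base_ids,
        traits=[p.trait],
    )
    return data, truth


def _pedigree_with_per_generation_sires(n_founders, generation_sizes, n_sires, seed):
    """Chain single-generation simulations so the sire-pool size can differ
    per generation (broad first generation, concentrated second)."""
    from .simulate import simulate_pedigree as sim_ped
    import pandas as pd
    from .types import Pedigree, UNKNOWN_PARENT

    if n_sires is None:
        return sim_ped(
            n_founders,
            len(generation_sizes),
            seed=seed,
            generation_sizes=generation_sizes,
        )
    rng = np.random.default_rng(seed)
    ped = sim_ped(n_founders, 0, seed=seed)
    table = ped.table
    for gen, (size, sires) in enumerate(zip(generation_sizes, n_sires), start=1):
        prev = table.loc[table["generation"] == gen - 1]
        males = prev.loc[prev["sex"] == "M", "animal_id"].to_numpy(dtype=object)
        females = prev.loc[prev["sex"] == "F", "animal_id"].to_numpy(dtype=object)
        if len(males) == 0 or len(females) == 0:
            raise ValueError("cannot mate: previous generation lacks one sex")
        if sires is not None and sires < len(males):
            males = rng.choice(males, size=sires, replace=False)
        sire_draw = rng.choice(males, size=size, replace=True)
        dam_draw = rng.choice(females, size=size, replace=True)
        start = len(table)
        rows = []
        for i in range(size):
            rows.append(
                (
                    f"A{start + i:06d}",
                    sire_draw[i],
                    dam_draw[i],
                    "M" if rng.random() < 0.5 else "F",
                    gen,
                )
            )
        table = pd.concat(
            [table, pd.DataFrame(rows, columns=table.columns)], ignore_index=True
        )
    return Pedigree(table)
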