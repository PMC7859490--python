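import numpy as np
import pandas as pd
import pytest

from panelgp import (
    GenotypeMatrix,
    Pedigree,
    annotate_markers,
    make_marker_map,
    simulate_genotypes,
    simulate_pedigree,
)


@pytest.fixture(scope="session")
def small_pedigree():
    """Deterministic 3-generation pedigree of ~60 animals."""
    return simulate_pedigree(20, 2, 2, seed=11)


@pytest.fixture(scope="session")
def small_genotypes(small_pedigree):
    mm = annotate_markers(make_marker_map(400, 4, 50, seed=5), seed=6)
    return simulate_genotypes(small_pedigree, mm, founder_ld_rho=0.5, seed=7)


@pytest.fixture(scope="session")
def founder_population():
    """500 unrelated animals, 2,000 independent-ish markers."""
    ped = simulate_pedigree(500, 0, seed=3)
    mm = annotate_markers(make_marker_map(2000, 5, 80, seed=4), seed=5)
    return ped, simulate_genotypes(ped, mm, founder_ld_rho=0.0, seed=6)


def genotypes_from_dosages(dosages, chrom=None, pos=None):
    """Hand-built GenotypeMatrix for arithmetic fixtures."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    markers = pd.DataFrame(
        {
            "marker_id": [f"M{j:04d}" for j in range(m)],
            "chrom": chrom,
            "pos_bp": pos,
            "ref_allele": "A",
            "alt_allele": "C",
            "anno_class": "IGR",
        }
    )
    return GenotypeMatrix(
        animal_ids=np.array([f"A{i:04d}" for i in range(n)], dtype=object),
        markers=markers,
        dosages=dosages,
    )


def pedigree_from_rows(rows):
    """rows: (animal, sire, dam, sex, generation) tuples."""
    return Pedigree(
        pd.DataFrame(
            rows, columns=["animal_id", "sire_id", "dam_id", "sex", "generation"]
        )
    )
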