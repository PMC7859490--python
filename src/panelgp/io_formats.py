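"""Readers/writers and run configuration.

Genotypes exchange as PLINK bed/bim/fam (variant-major bed; the bim A1
column holds the alt allele whose copies the dosages count, so round trips
are lossless including missing calls). Pedigree, phenotype, annotation and
result tables are plain TSV. Result files carry a ``# config_digest=`` header
comment so every output can be traced to the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    ANNOTATION_CLASSES,
    MISSING,
    GenotypeMatrix,
    Pedigree,
    UNKNOWN_PARENT,
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes, indexed by dosage of the A1 (alt) allele
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed and a stage label.

    The scheme is a SeedSequence keyed by (master, crc32(stage)); it is
    stable across processes so any stage can be re-run in isolation.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    n, m = genotypes.n_animals, genotypes.n_markers
    fam = pd.DataFrame(
        {
            "fid": genotypes.animal_ids,
            "iid": genotypes.animal_ids,
            "father": "0",
            "mother": "0",
            "sex": 0,
            "phen": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    mk = genotypes.markers
    bim = pd.DataFrame(
        {
            "chrom": mk["chrom"],
            "snp": mk["marker_id"],
            "cm": 0,
            "pos": mk["pos_bp"],
            "a1": mk["alt_allele"],
            "a2": mk["ref_allele"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    codes = np.empty((m, n), dtype=np.uint8)
    dosT = genotypes.dosages.T
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[dosT == dosage] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    quads = codes.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phen"], dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp": str, "pos": int, "a1": str, "a2": str},
    )
    if bim["snp"].duplicated().any():
        dups = sorted(set(bim.loc[bim["snp"].duplicated(), "snp"]))
        raise ValueError(f"duplicate marker ids in bim: {dups[:5]}")
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("bad bed magic bytes (not a variant-major PLINK bed)")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_variant:
        raise ValueError(
            f"bed payload is {body.size} bytes, expected {m * bytes_per_variant} "
            f"for {n} samples x {m} variants"
        )
    body = body.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    markers = pd.DataFrame(
        {
            "marker_id": bim["snp"],
            "chrom": bim["chrom"],
            "pos_bp": bim["pos"],
            "ref_allele": bim["a2"],
            "alt_allele": bim["a1"],
            "anno_class": "IGR",
        }
    )
    return GenotypeMatrix(
        animal_ids=fam["iid"].to_numpy(dtype=object),
        markers=markers,
        dosages=dosages,
    )


def write_grm_gcta(grm, prefix: str | Path) -> None:
    """Persist a relationship matrix in the GCTA binary-GRM layout:
    float32 row-wise lower triangle (diagonal included) in ``.grm.bin``
    plus a two-column id file in ``.grm.id``."""
    prefix = Path(prefix)
    n = grm.n
    tri = grm.values[np.tril_indices(n)].astype("<f4")
    Path(f"{prefix}.grm.bin").write_bytes(tri.tobytes())
    pd.DataFrame({"fid": grm.ids, "iid": grm.ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_gcta(prefix: str | Path):
    """Read a GCTA-layout binary GRM back into a RelationshipMatrix."""
    from .types import RelationshipMatrix

    prefix = Path(prefix)
    ids = pd.read_csv(
        f"{prefix}.grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )["iid"].to_numpy(dtype=object)
    n = len(ids)
    tri = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(
            f"GRM payload has {tri.size} entries, expected {n * (n + 1) // 2}"
        )
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = tri
    values = values + np.tril(values, -1).T
    return RelationshipMatrix(ids=ids, values=values, kind="GENOMIC_G")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_pedigree_tsv(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> Pedigree:
    """Read a pedigree TSV, normalising unknown-parent sentinels and
    repairing record order topologically (error if cyclic)."""
    tab = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"animal_id", "sire_id", "dam_id"}
    if not required <= set(tab.columns):
        raise ValueError(f"pedigree TSV needs columns {sorted(required)}")
    for col in ("sire_id", "dam_id"):
        tab[col] = tab[col].fillna(UNKNOWN_PARENT).replace(
            {"": UNKNOWN_PARENT, ".": UNKNOWN_PARENT, "NA": UNKNOWN_PARENT}
        )
    if "sex" not in tab.columns:
        tab["sex"] = "M"
    if "generation" in tab.columns:
        tab["generation"] = tab["generation"].astype(int)

    ids = set(tab["animal_id"])
    order: list[int] = []
    placed: set[str] = set()
    pending = list(tab.index)
    while pending:
        progressed = False
        rest = []
        for i in pending:
            row = tab.loc[i]
            parents = [p for p in (row["sire_id"], row["dam_id"])
                       if p != UNKNOWN_PARENT and p in ids]
            if all(p in placed for p in parents):
                order.append(i)
                placed.add(row["animal_id"])
                progressed = True
            else:
                rest.append(i)
        if not progressed:
            raise ValueError("pedigree contains a cycle: cannot order parents first")
        pending = rest
    tab = tab.loc[order].reset_index(drop=True)
    if "generation" not in tab.columns:
        gen = {}
        for row in tab.itertuples(index=False):
            ps = [gen.get(p, -1) for p in (row.sire_id, row.dam_id)]
            gen[row.animal_id] = max(ps) + 1
        tab["generation"] = [gen[a] for a in tab["animal_id"]]
    return Pedigree(tab[["animal_id", "sire_id", "dam_id", "sex", "generation"]])


def read_phenotypes_tsv(path, trait_cols=None) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", comment="#")
    if "animal_id" not in tab.columns:
        raise ValueError("phenotype TSV needs an animal_id column")
    tab["animal_id"] = tab["animal_id"].astype(str)
    for factor in ("sex", "contemporary_group"):
        if factor in tab.columns:
            sizes = tab[factor].value_counts()
            tiny = sizes[sizes < 2]
            if len(tiny):
                warnings.warn(
                    f"factor {factor!r} has levels with a single observation "
                    f"({list(tiny.index)[:5]}): their effects are inestimable",
                    stacklevel=2,
                )
    if trait_cols:
        missing = [c for c in trait_cols if c not in tab.columns]
        if missing:
            raise ValueError(f"trait columns absent from phenotype TSV: {missing}")
    return tab


def read_annotation_tsv(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"marker_id", "anno_class"} <= set(tab.columns):
        raise ValueError("annotation TSV needs marker_id and anno_class columns")
    bad = set(tab["anno_class"]) - set(ANNOTATION_CLASSES)
    if bad:
        raise ValueError(f"unknown annotation classes {sorted(bad)}")
    return tab


def apply_annotation(genotypes: GenotypeMatrix, annotation: pd.DataFrame) -> GenotypeMatrix:
    mapping = dict(zip(annotation["marker_id"], annotation["anno_class"]))
    markers = genotypes.markers.copy()
    markers["anno_class"] = [
        mapping.get(m, c) for m, c in zip(markers["marker_id"], markers["anno_class"])
    ]
    return GenotypeMatrix(genotypes.animal_ids, markers, genotypes.dosages)


def write_tsv(df: pd.DataFrame, path, digest: str | None = None) -> None:
    """TSV with an optional config-digest header comment; deterministic
    float formatting so identical runs produce identical bytes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if digest:
            fh.write(f"# config_digest={digest}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow standard SNP-array practice."""

    master_seed: int
    traits: list = field(default_factory=lambda: ["CWT"])
    maf_min: float = 0.01
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    max_missing: float = 0.10
    prune_r2: float = 0.95
    prune_window_variants: int = 100
    prune_window_kb: float = 5000.0
    prune_step_variants: int = 50
    grm_threshold: float = 0.30
    regions: list = field(default_factory=lambda: ["WGS"])
    k_grid: list = field(default_factory=lambda: [1000, 3000, 5000, 10000])
    n_folds: int = 10
    genotypes_prefix: str | None = None
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    annotation_path: str | None = None
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min", "max_missing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.prune_r2 <= 1.0):
            raise ValueError("prune_r2 outside [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.master_seed is None:
            raise ValueError("master_seed is mandatory")

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.master_seed, stage)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
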