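"""Core domain containers shared across the pipeline.

Genotypes are additive alt-allele dosages in {0, 1, 2} with ``MISSING`` (-1)
as the reserved sentinel for untyped calls; dosages are stored as ``int8``
and converted to float (with NaN for missing) only where arithmetic needs it.
Markers are carried as a pandas DataFrame so that position sorting, region
subsetting and annotation joins stay ordinary DataFrame operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

ANNOTATION_CLASSES = ("IGR", "ITR", "REG", "SYN", "NSY")
#: Composite regions resolvable to annotation-class subsets. WGS = every
#: marker; RSN = regulatory + synonymous + non-synonymous.
COMPOSITE_REGIONS = {
    "WGS": set(ANNOTATION_CLASSES),
    "RSN": {"REG", "SYN", "NSY"},
}

MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "ref_allele", "alt_allele", "anno_class"]

UNKNOWN_PARENT = "0"


def region_classes(region: str) -> set[str]:
    """Annotation classes making up ``region`` (a class name or composite)."""
    if region in COMPOSITE_REGIONS:
        return set(COMPOSITE_REGIONS[region])
    if region in ANNOTATION_CLASSES:
        return {region}
    raise ValueError(f"unknown genomic region {region!r}")


@dataclass(frozen=True)
class Pedigree:
    """Pedigree records ordered so that every parent precedes its offspring.

    ``table`` columns: animal_id, sire_id, dam_id, sex ('M'/'F'),
    generation (int >= 0). Unknown parents are the sentinel ``'0'``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = self.table
        seen: set[str] = set()
        for row in tab.itertuples(index=False):
            for parent in (row.sire_id, row.dam_id):
                if parent != UNKNOWN_PARENT and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {row.animal_id!r} does not precede it"
                    )
            if row.animal_id in seen:
                raise ValueError(f"duplicate animal id {row.animal_id!r}")
            seen.add(row.animal_id)

    @property
    def animal_ids(self) -> list[str]:
        return list(self.table["animal_id"])

    def __len__(self) -> int:
        return len(self.table)

    def subset_info(self, ids: list[str]) -> pd.DataFrame:
        sub = self.table.set_index("animal_id").loc[ids].reset_index()
        return sub


@dataclass
class GenotypeMatrix:
    """Animals x markers additive dosages with per-marker metadata.

    ``dosages`` is int8 with values in {0, 1, 2, MISSING}; rows follow
    ``animal_ids``, columns follow ``markers`` sorted by (chrom, pos_bp).
    """

    animal_ids: np.ndarray
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n != len(self.animal_ids):
            raise ValueError("dosage rows do not match animal_ids")
        if m != len(self.markers):
            raise ValueError("dosage columns do not match markers")
        chrom = self.markers["chrom"].to_numpy()
        pos = self.markers["pos_bp"].to_numpy()
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(m)):
            raise ValueError("markers must be sorted by (chrom, pos_bp)")
        if self.markers["marker_id"].duplicated().any():
            dups = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids: {sorted(set(dups))[:5]}")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker_id"].to_numpy()

    def dosages_float(self) -> np.ndarray:
        """Dosages as float64 with NaN in place of MISSING."""
        out = self.dosages.astype(np.float64)
        out[self.dosages == MISSING] = np.nan
        return out

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        """Column subset preserving genomic order."""
        wanted = set(marker_ids)
        mask = self.markers["marker_id"].isin(wanted).to_numpy()
        missing = wanted - set(self.markers.loc[mask, "marker_id"])
        if missing:
            raise KeyError(f"markers not present: {sorted(missing)[:5]}")
        return GenotypeMatrix(
            animal_ids=self.animal_ids,
            markers=self.markers.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    def subset_region(self, region: str) -> "GenotypeMatrix":
        classes = region_classes(region)
        mask = self.markers["anno_class"].isin(classes).to_numpy()
        return GenotypeMatrix(
            animal_ids=self.animal_ids,
            markers=self.markers.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    def subset_animals(self, ids) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        rows = np.array([index[a] for a in ids], dtype=int)
        return GenotypeMatrix(
            animal_ids=np.asarray(list(ids), dtype=object),
            markers=self.markers,
            dosages=self.dosages[rows],
        )


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric kinship matrix: pedigree-expected (A) or marker-realised (G)."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # PEDIGREE_A or GENOMIC_G
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=object))
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("relationship matrix shape does not match ids")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"animal {exc.args[0]!r} not in relationship matrix") from exc

    def subset(self, ids) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(
            ids=np.asarray(list(ids), dtype=object),
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic architecture of one simulated trait.

    effect_dist: ("normal", sd) or ("gamma", shape, scale) with random sign.
    target_h2 is the narrow-sense heritability of TBV within TBV+residual;
    pheno_mean/pheno_sd set the reporting scale of the final phenotype.
    """

    trait_name: str
    n_qtl: int
    effect_dist: tuple = ("normal", 1.0)
    target_h2: float = 0.33
    pheno_mean: float = 0.0
    pheno_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        if self.n_qtl > 0 and not (0.0 < self.target_h2 < 1.0):
            raise ValueError("target_h2 must lie strictly in (0, 1) when n_qtl > 0")
        if self.pheno_sd <= 0:
            raise ValueError("pheno_sd must be positive")
        if self.effect_dist[0] not in ("normal", "gamma"):
            raise ValueError(f"unknown effect distribution {self.effect_dist[0]!r}")


@dataclass
class TruthSet:
    """Ground truth of a simulated trait for recovery tests."""

    qtl_ids: list
    qtl_effects: np.ndarray
    true_breeding_values: pd.Series  # indexed by animal id
    true_fixed_effects: pd.Series | None = None
    realized_h2: float | None = None

    def rescaled(self, factor: float) -> "TruthSet":
        return TruthSet(
            qtl_ids=list(self.qtl_ids),
            qtl_effects=self.qtl_effects * factor,
            true_breeding_values=self.true_breeding_values * factor,
            true_fixed_effects=self.true_fixed_effects,
            realized_h2=self.realized_h2,
        )


@dataclass(frozen=True)
class PanelSet:
    """A base marker panel plus ranked pre-selected additions."""

    base_ids: tuple
    added_ids: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.base_ids) & set(self.added_ids)
        if overlap:
            raise ValueError(f"added markers overlap base panel: {sorted(overlap)[:5]}")

    @property
    def all_ids(self) -> tuple:
        return tuple(self.base_ids) + tuple(self.added_ids)

    @property
    def size(self) -> int:
        return len(self.base_ids) + len(self.added_ids)


def as_phenotype_table(df: pd.DataFrame, trait_cols: list[str]) -> pd.DataFrame:
    """Validate a phenotype table: one row per animal, factor columns present."""
    required = {"animal_id", "sex", "contemporary_group", "slaughter_age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    for col in trait_cols:
        if col not in df.columns:
            raise ValueError(f"trait column {col!r} absent")
    if df["animal_id"].duplicated().any():
        raise ValueError("duplicate animal ids in phenotype table")
    return df
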