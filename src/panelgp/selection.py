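"""Discovery/validation partitioning and GWAS-based variant pre-selection.

The discovery cohort is the set of animals with no relative at or above a
genomic-relationship threshold (default 0.30) anywhere in the population;
everyone else goes to the cross-validation cohort. Pre-selected markers are
the lowest-p GWAS hits of a region; when a hit already sits on the base
panel it is retained there and replaced by the next-ranked candidate so the
number of ADDED markers stays exactly k.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import PanelSet, RelationshipMatrix


def partition_discovery(
    G_base: RelationshipMatrix, threshold: float = 0.30
) -> tuple[list, list]:
    """Split animals into (discovery, cross-validation) by max off-diagonal G.

    An animal enters discovery iff its largest off-diagonal relationship to
    ANY other animal is strictly below ``threshold``.
    """
    v = G_base.values.copy()
    np.fill_diagonal(v, -np.inf)
    max_rel = v.max(axis=1)
    disc = max_rel < threshold
    discovery = [a for a, d in zip(G_base.ids, disc) if d]
    cv = [a for a, d in zip(G_base.ids, disc) if not d]
    if not discovery:
        raise ValueError("empty discovery set at this GRM threshold")
    return discovery, cv


def select_top_k(gwas_table: pd.DataFrame, k: int) -> list:
    """The k lowest-p markers, ties broken by (chrom, pos_bp)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ranked = gwas_table.sort_values(
        ["p_value", "chrom", "pos_bp"], kind="mergesort"
    )
    return ranked["marker_id"].head(k).tolist()


def rank_all(gwas_table: pd.DataFrame) -> list:
    """Full p-value ranking (for augmenting with overlap replacement)."""
    return select_top_k(gwas_table, len(gwas_table))


def augment_panel(
    base_ids, ranked_candidates, k: int, provenance: dict | None = None
) -> PanelSet:
    """Add the first k ranked candidates that are not already on the base
    panel (overlapping hits stay in the base set and are replaced by the
    next-ranked ones). Raises when the candidate list runs out."""
    base = tuple(base_ids)
    base_set = set(base)
    added: list = []
    seen: set = set()
    for mid in ranked_candidates:
        if len(added) == k:
            break
        if mid in base_set or mid in seen:
            continue
        added.append(mid)
        seen.add(mid)
    if len(added) < k:
        raise ValueError(
            f"candidate list exhausted: {k - len(added)} of {k} additions missing"
        )
    return PanelSet(base_ids=base, added_ids=tuple(added), provenance=provenance or {})


def combine_trait_sets(per_trait_panels: list[PanelSet]) -> PanelSet:
    """Union of the added markers across traits over a shared base panel.

    The union is deduplicated, so the combined size can fall below the sum
    of the per-trait k's; both the nominal and actual sizes are recorded.
    """
    if not per_trait_panels:
        raise ValueError("no panels to combine")
    base = per_trait_panels[0].base_ids
    for p in per_trait_panels[1:]:
        if tuple(p.base_ids) != tuple(base):
            raise ValueError("panels do not share the same base set")
    added: list = []
    seen: set = set()
    for p in per_trait_panels:
        for mid in p.added_ids:
            if mid not in seen:
                seen.add(mid)
                added.append(mid)
    nominal = sum(len(p.added_ids) for p in per_trait_panels)
    prov = {
        "traits": [p.provenance.get("trait") for p in per_trait_panels],
        "nominal_size": nominal,
        "actual_size": len(added),
    }
    return PanelSet(base_ids=tuple(base), added_ids=tuple(added), provenance=prov)


def random_panel(
    candidate_pool_ids, base_ids, k: int, seed: int = 0
) -> PanelSet:
    """k markers sampled uniformly without replacement from pool minus base."""
    base = tuple(base_ids)
    base_set = set(base)
    eligible = [m for m in candidate_pool_ids if m not in base_set]
    if len(eligible) < k:
        raise ValueError(f"pool has only {len(eligible)} eligible markers, need {k}")
    rng = np.random.default_rng(seed)
    added = list(rng.choice(np.asarray(eligible, dtype=object), size=k, replace=False))
    return PanelSet(
        base_ids=base,
        added_ids=tuple(added),
        provenance={"region": "RAN", "k": k, "seed": seed},
    )
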