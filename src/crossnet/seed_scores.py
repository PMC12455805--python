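"""Pairwise seed scores and module-linked seed complement listings.

Two indices summarize the metabolic interplay of an ordered (beneficiary A,
donor B) pair of networks:

* ``MI_Complementarity(A, B) = |Seeds_A ∩ NonSeeds_B| / |Seeds_A|`` — the
  fraction of A's required nutrients that B can synthesize on its own; an
  upper bound on cross-feeding potential.
* ``MI_Competition(A, B) = Σ_{c ∈ Seeds_A ∩ Seeds_B} C_A(c) / Σ_{c ∈ Seeds_A} C_A(c)``
  — the confidence-weighted overlap of the two seed sets; similarity of
  nutritional profiles and an upper bound on exploitative competition.

Both indices live in [0, 1]; the self-pair identities are
``MI_Complementarity(A, A) = 0`` and ``MI_Competition(A, A) = 1``.  The
competition numerator and denominator are weighted by the beneficiary-side
confidences.

Seed *complements* list the concrete compounds behind the complementarity
index — beneficiary seeds that are donor non-seeds — restricted to
compounds linked to a KEGG module via the user-supplied compound mapping,
translated to KEGG ids, and grouped per KEGG map (a compound linked to
several maps appears under each).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .seeds import SeedSet

__all__ = [
    "SeedScores",
    "SeedComplement",
    "CompoundMapping",
    "MappingRow",
    "mi_complementarity",
    "mi_competition",
    "compute_seed_scores",
    "seed_complements",
    "build_seed_map_url",
    "CROSS_FED_COLOR",
    "BENEFICIARY_PRODUCED_COLOR",
]

#: Cross-fed seed compounds are highlighted in red on KEGG maps; compounds
#: the beneficiary produces on its own in blue.
CROSS_FED_COLOR = "red"
BENEFICIARY_PRODUCED_COLOR = "blue"

_KEGG_SHOW_PATHWAY = "https://www.kegg.jp/kegg-bin/show_pathway?"


@dataclass(frozen=True)
class SeedScores:
    beneficiary_id: str
    donor_id: str
    mi_complementarity: float
    mi_competition: float


@dataclass(frozen=True)
class MappingRow:
    internal_id: str
    kegg_compound: str
    kegg_maps: tuple[str, ...]
    module_linked: bool


@dataclass(frozen=True)
class CompoundMapping:
    """Internal id ↔ KEGG compound ↔ KEGG map namespace translation.

    Rows flagged ``module_linked`` form the whitelist used when reporting
    seed complements; compounds without a KEGG translation still count in
    the MI indices, which operate on raw seed sets.
    """

    rows: tuple[MappingRow, ...]

    def __post_init__(self) -> None:
        ids = [r.internal_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate internal compound ids in mapping")

    def by_internal(self) -> dict[str, MappingRow]:
        return {r.internal_id: r for r in self.rows}

    def whitelist(self) -> frozenset[str]:
        return frozenset(r.internal_id for r in self.rows if r.module_linked)


@dataclass(frozen=True)
class SeedComplement:
    """Module-linked beneficiary seeds producible by the donor."""

    beneficiary_id: str
    donor_id: str
    compounds: tuple[tuple[str, str], ...]  # (internal id, KEGG compound id)
    kegg_maps: Mapping[str, frozenset[str]]  # map id -> KEGG compound subset
    category: str = "seed-complement"


def mi_complementarity(seeds_a: SeedSet, seeds_b: SeedSet) -> float:
    """Fraction of A's seeds among B's non-seeds (beneficiary A, donor B)."""
    sa = seeds_a.seed_compounds
    if not sa:
        raise ValueError(
            f"{seeds_a.network_id}: empty seed set, complementarity undefined"
        )
    return len(sa & seeds_b.non_seeds) / len(sa)


def mi_competition(seeds_a: SeedSet, seeds_b: SeedSet) -> float:
    """Confidence-weighted seed overlap of A with B, normalized on A."""
    sa = seeds_a.seed_compounds
    denom = seeds_a.confidence_sum()
    if not sa or denom <= 0:
        raise ValueError(
            f"{seeds_a.network_id}: empty seed set, competition undefined"
        )
    shared = sa & seeds_b.seed_compounds
    # confidences are sums of 1/k terms; guard against float spill past 1
    return min(1.0, sum(seeds_a.seeds[c] for c in shared) / denom)


def compute_seed_scores(beneficiary: SeedSet, donor: SeedSet) -> SeedScores:
    return SeedScores(
        beneficiary_id=beneficiary.network_id,
        donor_id=donor.network_id,
        mi_complementarity=mi_complementarity(beneficiary, donor),
        mi_competition=mi_competition(beneficiary, donor),
    )


def seed_complements(
    beneficiary: SeedSet, donor: SeedSet, mapping: CompoundMapping
) -> SeedComplement:
    """Beneficiary seeds that are donor non-seeds, module-linked only.

    Compounds are translated to KEGG ids and grouped by KEGG map; a
    compound linked to several maps appears under each.  An empty overlap
    yields a record with no compounds.
    """
    rows = mapping.by_internal()
    overlap = (
        beneficiary.seed_compounds & donor.non_seeds & mapping.whitelist()
    )
    compounds = tuple(
        (cid, rows[cid].kegg_compound) for cid in sorted(overlap)
    )
    maps: dict[str, set[str]] = {}
    for cid in sorted(overlap):
        for map_id in rows[cid].kegg_maps:
            maps.setdefault(map_id, set()).add(rows[cid].kegg_compound)
    return SeedComplement(
        beneficiary_id=beneficiary.network_id,
        donor_id=donor.network_id,
        compounds=compounds,
        kegg_maps={m: frozenset(v) for m, v in sorted(maps.items())},
    )


def build_seed_map_url(
    map_id: str,
    beneficiary_related: Iterable[str],
    cross_fed_seeds: Iterable[str],
) -> str:
    """KEGG show_pathway URL highlighting a seed complement on a map.

    Cross-fed seed compounds carry the red token; compounds the beneficiary
    produces on its own the blue token.  Compounds are sorted, so repeated
    calls return byte-identical URLs.  A compound in both sets is treated
    as cross-fed.
    """
    fed = frozenset(cross_fed_seeds)
    own = frozenset(beneficiary_related) - fed
    parts = [map_id]
    for cid in sorted(own | fed):
        color = CROSS_FED_COLOR if cid in fed else BENEFICIARY_PRODUCED_COLOR
        parts.append(f"{cid}%09{color}")
    return _KEGG_SHOW_PATHWAY + "/".join(parts)
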