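"""Assemble the annotated co-occurrence network.

The input is an undirected, signed co-occurrence network over taxa.  Nodes
gain trait attributes and genome mappings; for every associated node pair
where both endpoints map to at least one genome, each ordered genome
combination is evaluated and a *directed* complementarity edge (donor =
source, beneficiary = target) is added per direction that has at least one
pathway or seed complement.  Each complementarity edge carries sub-tables
keyed by ordered genome pair.  Original co-occurrence edges are preserved
untouched — annotation never deletes, reweights, or duplicates them, and
re-annotating an annotated network with the same inputs is a no-op on the
edge set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .complementarity import PathwayComplement
from .seed_scores import SeedComplement, SeedScores

__all__ = [
    "CooccurrenceNetwork",
    "TraitTable",
    "TRAIT_GROUPS",
    "annotate_network",
    "filter_nodes_by_traits",
    "COOCCURRENCE_KEY",
    "COMPLEMENTARITY_KEY",
]

COOCCURRENCE_KEY = "cooccurrence"
COMPLEMENTARITY_KEY = "complementarity"
TRAIT_GROUPS = ("lifestyle", "biogeochemical", "metabolite", "other")


@dataclass
class CooccurrenceNetwork:
    """Undirected signed association network over taxa.

    ``taxonomy`` maps node id → taxonomy string; edges carry finite signed
    weights (positive co-occurrence vs mutual exclusion).
    """

    graph: nx.Graph
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-edge on node {u!r}")
            w = data.get("weight", 1.0)
            if not math.isfinite(w):
                raise ValueError(f"non-finite weight on edge ({u}, {v})")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (u, v, d.get("weight", 1.0)) for u, v, d in self.graph.edges(data=True)
        ]


@dataclass
class TraitTable:
    """Phenotypic trait calls per genome (or node).

    ``values[genome][trait]`` is True/False/None (None = unknown, distinct
    from absent).  Every declared trait belongs to one of the groups
    lifestyle / biogeochemical / metabolite / other; ``scores`` optionally
    carries prediction confidences.
    """

    values: dict[str, dict[str, bool | None]]
    groups: dict[str, str] = field(default_factory=dict)
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        declared = self.declared_traits()
        for trait in declared:
            self.groups.setdefault(trait, "other")
        for trait, group in self.groups.items():
            if group not in TRAIT_GROUPS:
                raise ValueError(
                    f"trait {trait!r} has unknown group {group!r}; "
                    f"expected one of {TRAIT_GROUPS}"
                )

    def declared_traits(self) -> list[str]:
        traits: set[str] = set(self.groups)
        for row in self.values.values():
            traits.update(row)
        return sorted(traits)

    def value(self, entity: str, trait: str) -> bool | None:
        return self.values.get(entity, {}).get(trait)


def _cooccurrence_sign(weight: float) -> str:
    return "positive co-occurrence" if weight >= 0 else "mutual exclusion"


def _extract_cooccurrence(
    network: CooccurrenceNetwork | nx.MultiDiGraph,
) -> tuple[nx.Graph, dict[str, str]]:
    """Accept a raw network or an already-annotated one (idempotence)."""
    if isinstance(network, CooccurrenceNetwork):
        return network.graph, dict(network.taxonomy)
    g = nx.Graph()
    taxonomy: dict[str, str] = {}
    for n, data in network.nodes(data=True):
        g.add_node(n)
        if "taxonomy" in data:
            taxonomy[n] = data["taxonomy"]
    for u, v, key, data in network.edges(keys=True, data=True):
        if data.get("interaction_type") == "co-occurrence":
            g.add_edge(u, v, weight=data.get("weight", 1.0))
    return g, taxonomy


def _node_trait_vector(
    genome_ids: Sequence[str], traits: TraitTable
) -> dict[str, bool | None]:
    """Merge per-genome calls: present if any genome has it, unknown if all
    genomes are unknown, absent otherwise."""
    merged: dict[str, bool | None] = {}
    for trait in traits.declared_traits():
        calls = [traits.value(g, trait) for g in genome_ids]
        known = [c for c in calls if c is not None]
        if not known:
            merged[trait] = None
        else:
            merged[trait] = any(known)
    return merged


def annotate_network(
    network: CooccurrenceNetwork | nx.MultiDiGraph,
    node_genomes: Mapping[str, Sequence[str]],
    traits: TraitTable | None = None,
    pathway_complements: Iterable[PathwayComplement] = (),
    seed_scores: Iterable[SeedScores] = (),
    seed_complements: Iterable[SeedComplement] = (),
    clusters: Mapping[str, str] | None = None,
) -> nx.MultiDiGraph:
    """Build the annotated network.

    Co-occurrence edges are copied unchanged (one edge per undirected
    association, typed ``co-occurrence`` with a sign attribute).  For every
    associated node pair whose endpoints both map to genomes, all ordered
    genome combinations are looked up in the supplied pathway/seed results;
    a directed ``complementarity`` edge is added per direction with at
    least one hit, with per-genome-pair sub-tables.

    Raises
    ------
    ValueError
        If a complement references a genome id not mapped to any node.
    """
    base, taxonomy = _extract_cooccurrence(network)
    mapped: set[str] = set()
    for gids in node_genomes.values():
        mapped.update(gids)

    pc_index: dict[tuple[str, str], list[PathwayComplement]] = {}
    for pc in pathway_complements:
        if pc.beneficiary_id not in mapped or pc.donor_id not in mapped:
            raise ValueError(
                f"pathway complement references unmapped genome "
                f"({pc.beneficiary_id!r}, {pc.donor_id!r})"
            )
        pc_index.setdefault((pc.donor_id, pc.beneficiary_id), []).append(pc)
    ss_index: dict[tuple[str, str], SeedScores] = {}
    for ss in seed_scores:
        ss_index[(ss.donor_id, ss.beneficiary_id)] = ss
    sc_index: dict[tuple[str, str], SeedComplement] = {}
    for sc in seed_complements:
        if sc.beneficiary_id not in mapped or sc.donor_id not in mapped:
            raise ValueError(
                f"seed complement references unmapped genome "
                f"({sc.beneficiary_id!r}, {sc.donor_id!r})"
            )
        sc_index[(sc.donor_id, sc.beneficiary_id)] = sc

    out = nx.MultiDiGraph()
    for n in base.nodes:
        gids = sorted(node_genomes.get(n, []))
        attrs: dict = {
            "taxonomy": taxonomy.get(n, ""),
            "genomes": gids,
        }
        if traits is not None:
            attrs["traits"] = _node_trait_vector(gids, traits)
            attrs["trait_scores"] = {
                t: traits.scores[(g, t)]
                for g in gids
                for t in traits.declared_traits()
                if (g, t) in traits.scores
            }
        if clusters is not None and n in clusters:
            attrs["cluster"] = clusters[n]
        out.add_node(n, **attrs)

    for u, v, data in base.edges(data=True):
        w = data.get("weight", 1.0)
        out.add_edge(
            u,
            v,
            key=COOCCURRENCE_KEY,
            interaction_type="co-occurrence",
            weight=w,
            sign=_cooccurrence_sign(w),
        )
        for donor_node, benef_node in ((u, v), (v, u)):
            donors = node_genomes.get(donor_node, [])
            benefs = node_genomes.get(benef_node, [])
            if not donors or not benefs:
                continue
            pc_tables: dict[str, list[PathwayComplement]] = {}
            ss_tables: dict[str, SeedScores] = {}
            sc_tables: dict[str, SeedComplement] = {}
            for gd, gb in product(sorted(donors), sorted(benefs)):
                pair_key = f"{gd}->{gb}"
                if (gd, gb) in pc_index:
                    pc_tables[pair_key] = pc_index[(gd, gb)]
                if (gd, gb) in ss_index:
                    ss_tables[pair_key] = ss_index[(gd, gb)]
                if (gd, gb) in sc_index and sc_index[(gd, gb)].compounds:
                    sc_tables[pair_key] = sc_index[(gd, gb)]
            if pc_tables or sc_tables:
                out.add_edge(
                    donor_node,
                    benef_node,
                    key=COMPLEMENTARITY_KEY,
                    interaction_type="complementarity",
                    donor=donor_node,
                    beneficiary=benef_node,
                    pathway_complements=pc_tables,
                    seed_scores=ss_tables,
                    seed_complements=sc_tables,
                )
    return out


def filter_nodes_by_traits(
    annotated: nx.MultiDiGraph,
    traits: Iterable[str],
    mode: str = "ANY",
    trait_table: TraitTable | None = None,
) -> set[str]:
    """Nodes carrying at least one (ANY/OR) or every (ALL/AND) trait.

    Unknown counts as not-present.  Trait names must be declared (in the
    trait table when given, otherwise anywhere in the node annotations).
    """
    mode = mode.upper()
    if mode not in ("ANY", "ALL"):
        raise ValueError(f"mode must be ANY or ALL, got {mode!r}")
    wanted = list(traits)
    declared: set[str] = set()
    if trait_table is not None:
        declared = set(trait_table.declared_traits())
    else:
        for _, data in annotated.nodes(data=True):
            declared.update(data.get("traits", {}))
    unknown = [t for t in wanted if t not in declared]
    if unknown:
        raise ValueError(f"undeclared trait name(s): {unknown}")
    if not wanted:
        return set()
    out: set[str] = set()
    for n, data in annotated.nodes(data=True):
        vec = data.get("traits", {})
        present = [vec.get(t) is True for t in wanted]
        if (mode == "ANY" and any(present)) or (mode == "ALL" and all(present)):
            out.add(n)
    return out
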