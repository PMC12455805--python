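"""Seed sets of metabolic networks via compound-graph condensation.

The *seed set* of a metabolic network is the minimal set of compounds that
cannot be synthesized from other compounds in the network — a proxy for the
nutrients the organism must obtain exogenously.  Operationally: build the
directed compound graph (substrate → product per reaction, both directions
for reversible reactions), condense it into strongly connected components
(SCCs), and take every compound belonging to a source SCC (zero in-degree in
the condensation DAG).  Seeds in an interdependent SCC of size ``k`` each
carry confidence ``C = 1/k``; the confidences within one source SCC sum
to 1.  All remaining compounds form the *non-seed set* — what the network
can produce on its own.

Graph semantics are plain substrate→product reachability (no AND-hypergraph
firing rule).  ModelSEED-style compartment suffixes (``_c0``, ``_e0``) are
stripped by default so a compound is a single node regardless of
compartment, and biomass/exchange pseudo-reactions are dropped before graph
construction; both rules are configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Reaction",
    "MetabolicNetwork",
    "SeedSet",
    "build_compound_graph",
    "condense_sccs",
    "compute_seed_set",
    "DEFAULT_COMPARTMENT_RE",
    "DEFAULT_PSEUDO_REACTION_RE",
]

#: ModelSEED-style compartment suffix, e.g. ``cpd00001_c0`` -> ``cpd00001``.
DEFAULT_COMPARTMENT_RE = r"_[a-zA-Z]\d*$"
#: Biomass/exchange pseudo-reactions carry no biochemistry.
DEFAULT_PSEUDO_REACTION_RE = r"(?i)^(bio\d*|biomass.*|EX_.*|SK_.*|DM_.*)$"


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False


@dataclass(frozen=True)
class MetabolicNetwork:
    """A reaction list plus its compound universe.

    ``compounds`` may include isolated compounds that no reaction touches;
    every substrate/product must be a member.
    """

    network_id: str
    compounds: frozenset[str]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.reaction_id in seen:
                raise ValueError(
                    f"{self.network_id}: duplicate reaction id {rxn.reaction_id}"
                )
            seen.add(rxn.reaction_id)
            unknown = (rxn.substrates | rxn.products) - self.compounds
            if unknown:
                raise ValueError(
                    f"{self.network_id}: reaction {rxn.reaction_id} references "
                    f"unknown compounds {sorted(unknown)}"
                )


@dataclass(frozen=True)
class SeedSet:
    """Seeds with confidences, the non-seed set, and SCC provenance."""

    network_id: str
    seeds: Mapping[str, float]
    non_seeds: frozenset[str]
    scc_of: Mapping[str, int]
    source_sccs: tuple[int, ...]

    @property
    def seed_compounds(self) -> frozenset[str]:
        return frozenset(self.seeds)

    def confidence_sum(self) -> float:
        return sum(self.seeds.values())


def normalize_network(
    network: MetabolicNetwork,
    compartment_re: str | None = DEFAULT_COMPARTMENT_RE,
    pseudo_reaction_re: str | None = DEFAULT_PSEUDO_REACTION_RE,
) -> MetabolicNetwork:
    """Strip compartment suffixes and drop pseudo-reactions.

    Pass ``None`` for either pattern to disable that rule.  Reactions left
    with an empty substrate or product side after normalization (exchange
    stubs) are removed.
    """
    comp = re.compile(compartment_re) if compartment_re else None
    pseudo = re.compile(pseudo_reaction_re) if pseudo_reaction_re else None

    def fix(cid: str) -> str:
        return comp.sub("", cid) if comp else cid

    reactions = []
    for rxn in network.reactions:
        if pseudo and pseudo.match(rxn.reaction_id):
            continue
        subs = frozenset(fix(c) for c in rxn.substrates)
        prods = frozenset(fix(c) for c in rxn.products)
        reactions.append(Reaction(rxn.reaction_id, subs, prods, rxn.reversible))
    compounds = frozenset(fix(c) for c in network.compounds)
    return MetabolicNetwork(network.network_id, compounds, tuple(reactions))


def build_compound_graph(network: MetabolicNetwork) -> nx.DiGraph:
    """Directed compound graph: substrate → product edges per reaction.

    Reversible reactions contribute edges in both directions.  Parallel
    edges collapse; a compound appearing on both sides of one reaction
    yields no self-loop.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.compounds)
    for rxn in network.reactions:
        for s in rxn.substrates:
            for p in rxn.products:
                if s == p:
                    continue
                g.add_edge(s, p)
                if rxn.reversible:
                    g.add_edge(p, s)
    return g


def condense_sccs(graph: nx.DiGraph) -> tuple[dict[str, int], nx.DiGraph]:
    """SCC partition and the (acyclic) condensation DAG.

    Returns ``(scc_of, condensation)`` where ``scc_of`` maps each compound
    to its SCC id and each condensation node carries its ``members`` set.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty compound graph")
    condensation = nx.condensation(graph)
    scc_of = dict(condensation.graph["mapping"])
    return scc_of, condensation


def compute_seed_set(
    network: MetabolicNetwork,
    exclude_compounds: Iterable[str] = (),
    normalize: bool = True,
    compartment_re: str | None = DEFAULT_COMPARTMENT_RE,
    pseudo_reaction_re: str | None = DEFAULT_PSEUDO_REACTION_RE,
) -> SeedSet:
    """Seed set of a metabolic network.

    Seeds are the compounds in source SCCs of the condensation; each seed's
    confidence is ``1 / |SCC|``.  ``exclude_compounds`` removes currency
    metabolites from the graph before the analysis (no filtering happens by
    default).

    Raises
    ------
    ValueError
        On an empty network (no compounds after normalization/exclusion).
    """
    if normalize:
        network = normalize_network(network, compartment_re, pseudo_reaction_re)
    excluded = frozenset(exclude_compounds)
    graph = build_compound_graph(network)
    graph.remove_nodes_from(excluded)
    if graph.number_of_nodes() == 0:
        raise ValueError(f"{network.network_id}: network has no compounds")
    scc_of, condensation = condense_sccs(graph)
    seeds: dict[str, float] = {}
    source_sccs: list[int] = []
    for scc_id in condensation.nodes:
        if condensation.in_degree(scc_id) == 0:
            members = condensation.nodes[scc_id]["members"]
            source_sccs.append(scc_id)
            conf = 1.0 / len(members)
            for compound in members:
                seeds[compound] = conf
    non_seeds = frozenset(graph.nodes) - frozenset(seeds)
    return SeedSet(
        network_id=network.network_id,
        seeds=seeds,
        non_seeds=non_seeds,
        scc_of=scc_of,
        source_sccs=tuple(sorted(source_sccs)),
    )
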