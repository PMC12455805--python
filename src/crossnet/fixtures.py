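"""Seeded synthetic-data generators with planted ground truth.

Every input the package consumes can be generated here deterministically:
module definitions with a known alternative count, genome pairs with a
planted complement, metabolic networks with a planted DAG-of-SCCs seed
structure, and annotated communities with planted cluster-trait
enrichments.  All randomness flows through one ``numpy.random.Generator``
per call, seeded explicitly; identical parameters and seed give identical
outputs.

KO identifiers are minted sequentially and uniquely per definition, so
per-step options never share a KO and the planted alternative count is
exactly the product of per-step option counts.  Decoy KOs handed to donor
genomes come from a disjoint range and can never complete a module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .annotate import CooccurrenceNetwork, TraitTable
from .kegg_modules import (
    Alternative,
    Complex,
    Expr,
    Leaf,
    ModuleDefinition,
    Optional_,
    Or,
)
from .seed_scores import CompoundMapping, MappingRow
from .seeds import MetabolicNetwork, Reaction

__all__ = [
    "gen_module_definition",
    "gen_genome_pair",
    "gen_metabolic_network",
    "gen_random_scc_spec",
    "gen_annotated_community",
    "gen_fixture_dir",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# module definitions
# ---------------------------------------------------------------------------


class _KoMinter:
    """Sequential unique KO ids; decoys come from the disjoint 9xxxx range."""

    def __init__(self, start: int = 1) -> None:
        self.next_id = start
        self.next_decoy = 90000

    def ko(self) -> str:
        ko = f"K{self.next_id:05d}"
        self.next_id += 1
        if self.next_id >= 90000:
            raise RuntimeError("KO id space exhausted")
        return ko

    def decoy(self) -> str:
        ko = f"K{self.next_decoy:05d}"
        self.next_decoy += 1
        return ko


def gen_module_definition(
    rng: int | np.random.Generator,
    n_steps: int | None = None,
    options_per_step: Sequence[int] | None = None,
    complex_prob: float = 0.3,
    optional_prob: float = 0.2,
    gap_prob: float = 0.05,
    max_options: int = 4,
    max_complex_size: int = 3,
    module_id: str = "MSYN",
    ko_start: int = 1,
) -> tuple[str, int]:
    """A random module definition with an exactly known alternative count.

    Returns ``(definition string, planted alternative count)`` where the
    count is the product of per-step option counts.  Complexes inflate
    option size, not count; optional members and gap steps contribute no
    KOs and never change the count.
    """
    r = _rng(rng)
    minter = _KoMinter(start=ko_start)
    if options_per_step is None:
        if n_steps is None:
            n_steps = int(r.integers(1, 5))
        counts = [int(r.integers(1, max_options + 1)) for _ in range(n_steps)]
    else:
        counts = [int(c) for c in options_per_step]
        if any(c < 1 for c in counts):
            raise ValueError("every step needs >= 1 option")
    steps: list[Expr] = []
    planted = 1
    for n_opts in counts:
        if n_opts == 1 and r.random() < gap_prob:
            steps.append(Leaf("--"))
            continue
        options: list[Expr] = []
        for _ in range(n_opts):
            if r.random() < complex_prob:
                size = int(r.integers(2, max_complex_size + 1))
                members: list[Expr] = [Leaf(minter.ko()) for _ in range(size)]
                if r.random() < optional_prob:
                    members.append(Optional_(Leaf(minter.ko())))
                options.append(Complex(tuple(members)))
            else:
                options.append(Leaf(minter.ko()))
        steps.append(options[0] if n_opts == 1 else Or(tuple(options)))
        planted *= n_opts
    definition = ModuleDefinition(module_id=module_id, raw="", steps=tuple(steps))
    return definition.normalized(), planted


def gen_genome_pair(
    alternative: Alternative,
    k_missing: int,
    rng: int | np.random.Generator,
    n_decoys: int = 5,
) -> tuple[frozenset[str], frozenset[str]]:
    """A (beneficiary, donor) KO-set pair with a planted complement.

    The beneficiary holds the alternative minus ``k_missing`` randomly
    chosen KOs; the donor holds exactly those plus decoy KOs from a range
    never used in definitions.
    """
    r = _rng(rng)
    kos = sorted(alternative.ko_set)
    if not 1 <= k_missing <= len(kos):
        raise ValueError(
            f"k_missing must be in [1, {len(kos)}], got {k_missing}"
        )
    missing = set(r.choice(kos, size=k_missing, replace=False).tolist())
    beneficiary = frozenset(alternative.ko_set) - missing
    minter = _KoMinter()
    decoys = {minter.decoy() for _ in range(n_decoys)}
    return beneficiary, frozenset(missing) | decoys - beneficiary


# ---------------------------------------------------------------------------
# metabolic networks
# ---------------------------------------------------------------------------


def gen_random_scc_spec(
    rng: int | np.random.Generator,
    max_sccs: int = 8,
    max_size: int = 6,
    edge_prob: float = 0.4,
) -> tuple[list[int], list[tuple[int, int]]]:
    """Random SCC sizes and a forward-directed (hence acyclic) wiring."""
    r = _rng(rng)
    n = int(r.integers(1, max_sccs + 1))
    sizes = [int(r.integers(1, max_size + 1)) for _ in range(n)]
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if r.random() < edge_prob
    ]
    return sizes, edges


def gen_metabolic_network(
    scc_sizes: Sequence[int],
    dag_edges: Sequence[tuple[int, int]],
    reversible_fraction: float = 0.5,
    rng: int | np.random.Generator = 0,
    network_id: str = "net",
) -> tuple[MetabolicNetwork, dict[str, float]]:
    """A metabolic network whose compound graph has a planted SCC structure.

    Each planted SCC of size >= 2 is realized as either a reversible chain
    or an irreversible cycle (chosen with ``reversible_fraction``); the
    SCCs are wired with irreversible reactions along the given DAG edges.
    Returns the network and the planted seeds: every member of a DAG-source
    SCC with confidence ``1/|SCC|``.

    Raises
    ------
    ValueError
        If ``dag_edges`` contains a cycle (the planted structure would not
        be a DAG of SCCs).
    """
    if not scc_sizes:
        raise ValueError("scc_sizes must be nonempty")
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(scc_sizes)))
    dag.add_edges_from(dag_edges)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("dag_edges must form an acyclic SCC wiring")
    r = _rng(rng)
    members: list[list[str]] = []
    counter = 0
    for size in scc_sizes:
        group = [f"C{counter + i:04d}" for i in range(size)]
        counter += size
        members.append(group)
    reactions: list[Reaction] = []

    def rid() -> str:
        return f"R{len(reactions):04d}"

    for group in members:
        if len(group) < 2:
            continue
        if r.random() < reversible_fraction:
            for a, b in zip(group, group[1:]):
                reactions.append(Reaction(rid(), frozenset({a}), frozenset({b}), True))
        else:
            cycle = group + [group[0]]
            for a, b in zip(cycle, cycle[1:]):
                reactions.append(Reaction(rid(), frozenset({a}), frozenset({b}), False))
    for i, j in dag_edges:
        a = members[i][int(r.integers(len(members[i])))]
        b = members[j][int(r.integers(len(members[j])))]
        reactions.append(Reaction(rid(), frozenset({a}), frozenset({b}), False))
    compounds = frozenset(c for group in members for c in group)
    network = MetabolicNetwork(network_id, compounds, tuple(reactions))
    sources = [i for i in dag.nodes if dag.in_degree(i) == 0]
    planted = {
        c: 1.0 / len(members[i]) for i in sources for c in members[i]
    }
    return network, planted


# ---------------------------------------------------------------------------
# annotated communities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEnrichment:
    cluster: str
    trait: str
    direction: str = "enriched"


def gen_annotated_community(
    n_nodes: int,
    n_clusters: int,
    trait_effect: float = 0.8,
    rng: int | np.random.Generator = 0,
    n_traits: int = 5,
    background_prob: float = 0.2,
    within_edge_prob: float = 0.3,
    between_edge_prob: float = 0.05,
) -> tuple[CooccurrenceNetwork, TraitTable, dict[str, str], list[PlantedEnrichment]]:
    """A community with planted cluster-trait enrichment signal.

    Trait ``i`` (for ``i < n_clusters``) is drawn with probability
    ``trait_effect`` inside cluster ``i`` and ``background_prob`` elsewhere;
    remaining traits are background everywhere.  Edges are denser within
    clusters (positive weights) than between (mixed sign).  The planted
    list names the elevated (cluster, trait) pairs and is empty when
    ``trait_effect`` equals the background (a null community).
    """
    if n_nodes < 2 * n_clusters:
        raise ValueError("need n_nodes >= 2 * n_clusters")
    r = _rng(rng)
    nodes = [f"node{i:03d}" for i in range(n_nodes)]
    clusters = {n: f"c{i % n_clusters}" for i, n in enumerate(nodes)}
    traits = [f"trait{i:02d}" for i in range(n_traits)]
    values: dict[str, dict[str, bool | None]] = {}
    for node in nodes:
        row: dict[str, bool | None] = {}
        for i, trait in enumerate(traits):
            elevated = i < n_clusters and clusters[node] == f"c{i}"
            p = trait_effect if elevated else background_prob
            row[trait] = bool(r.random() < p)
        values[node] = row
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            same = clusters[u] == clusters[v]
            if r.random() < (within_edge_prob if same else between_edge_prob):
                w = (
                    abs(r.normal(0.5, 0.2))
                    if same
                    else float(r.normal(0.0, 0.3))
                )
                g.add_edge(u, v, weight=float(w))
    taxonomy = {
        n: (
            "d__bacteria;p__synthetica;c__ficta;o__fictales;"
            f"f__fictaceae;g__genus{i % 7};s__genus{i % 7} species{i}"
        )
        for i, n in enumerate(nodes)
    }
    planted = (
        [
            PlantedEnrichment(f"c{i}", traits[i])
            for i in range(min(n_clusters, n_traits))
        ]
        if trait_effect > background_prob
        else []
    )
    network = CooccurrenceNetwork(graph=g, taxonomy=taxonomy)
    table = TraitTable(values=values, groups={t: "other" for t in traits})
    return network, table, clusters, planted


# ---------------------------------------------------------------------------
# full fixture directory
# ---------------------------------------------------------------------------


def gen_fixture_dir(
    outdir: str | Path,
    seed: int = 0,
    n_taxa: int = 12,
    n_modules: int = 4,
    n_clusters: int = 2,
    trait_effect: float = 0.8,
) -> dict:
    """Emit a self-contained fixture directory exercising the whole tool.

    Writes ``modules.tsv``, ``genomes.tsv``, ``reactions/*.tsv``,
    ``mapping.tsv``, ``network.tsv``, ``node_taxonomy.tsv``,
    ``genome_index.tsv``, ``traits.tsv``, ``clusters.tsv`` and
    ``truth.json`` (planted complements, seeds and enrichments).  Returns
    the truth dictionary.
    """
    from . import io as cio
    from .kegg_modules import enumerate_alternatives, parse_module_definition

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "reactions").mkdir(exist_ok=True)
    r = np.random.default_rng(seed)

    network, trait_table, clusters, planted_enr = gen_annotated_community(
        n_taxa, n_clusters, trait_effect=trait_effect, rng=r
    )
    nodes = network.nodes
    genome_of = {n: f"G{i:03d}" for i, n in enumerate(nodes)}

    # module set: re-id and parse each generated definition
    modules = []
    for i in range(n_modules):
        # disjoint KO ranges per module so donations for one module can
        # never complete another
        raw, count = gen_module_definition(
            r, module_id=f"M{i:05d}", ko_start=1 + i * 2000
        )
        definition = parse_module_definition(
            f"M{i:05d}", raw, name=f"synthetic module {i}", category="synthetic"
        )
        modules.append((definition, enumerate_alternatives(definition), count))
    cio.write_module_table(outdir / "modules.tsv", [m[0] for m in modules])

    # genomes: each holds one complete alternative per module, except that
    # for even nodes one module is left incomplete with a planted complement
    # suppliable by the next node's genome
    genomes: dict[str, set[str]] = {genome_of[n]: set() for n in nodes}
    planted_complements = []
    for idx, node in enumerate(nodes):
        gid = genome_of[node]
        for m_i, (definition, alts, _) in enumerate(modules):
            alt = alts[int(r.integers(len(alts)))]
            if m_i == idx % n_modules and len(alt.ko_set) >= 2:
                k = int(r.integers(1, min(4, len(alt.ko_set)) + 1))
                beneficiary, donor_extra = gen_genome_pair(alt, k, r)
                genomes[gid] |= set(beneficiary)
                partner = genome_of[nodes[(idx + 1) % len(nodes)]]
                genomes[partner] |= set(alt.ko_set)
                planted_complements.append(
                    {
                        "beneficiary": gid,
                        "donor": partner,
                        "module": definition.module_id,
                        "k_missing": len(alt.ko_set - beneficiary),
                    }
                )
            else:
                genomes[gid] |= set(alt.ko_set)
    cio.write_ko_table(outdir / "genomes.tsv", genomes)

    # metabolic networks + planted seeds
    planted_seeds: dict[str, dict[str, float]] = {}
    all_compounds: set[str] = set()
    for node in nodes:
        gid = genome_of[node]
        sizes, edges = gen_random_scc_spec(r)
        net, seeds = gen_metabolic_network(
            sizes, edges, rng=r, network_id=gid
        )
        cio.write_reaction_tsv(outdir / "reactions" / f"{gid}.tsv", net)
        planted_seeds[gid] = seeds
        all_compounds |= net.compounds

    # compound namespace mapping: internal id -> fake KEGG compound/map ids
    rows = []
    for i, cid in enumerate(sorted(all_compounds)):
        maps = tuple(
            f"map{int(r.integers(1, 6)):05d}"
            for _ in range(int(r.integers(1, 3)))
        )
        rows.append(
            MappingRow(
                internal_id=cid,
                kegg_compound=f"C{10000 + i:05d}",
                kegg_maps=tuple(sorted(set(maps))),
                module_linked=bool(r.random() < 0.7),
            )
        )
    cio.write_compound_mapping(outdir / "mapping.tsv", CompoundMapping(tuple(rows)))

    # network, taxonomy, genome index, traits, clusters
    with open(outdir / "network.tsv", "w", encoding="utf-8") as fh:
        for u, v, w in network.edges():
            fh.write(f"{u}\t{v}\t{w:.6g}\n")
    with open(outdir / "node_taxonomy.tsv", "w", encoding="utf-8") as fh:
        for n in nodes:
            fh.write(f"{n}\t{network.taxonomy[n]}\n")
    with open(outdir / "genome_index.tsv", "w", encoding="utf-8") as fh:
        for n in nodes:
            fh.write(f"{network.taxonomy[n]}\t{genome_of[n]}\n")
    # trait calls are generated per node; key them by genome for the tool
    genome_traits = TraitTable(
        values={genome_of[n]: trait_table.values[n] for n in nodes},
        groups=dict(trait_table.groups),
    )
    cio.write_traits_tsv(outdir / "traits.tsv", genome_traits)
    # node-keyed copy for direct cluster-trait enrichment runs
    cio.write_traits_tsv(outdir / "node_traits.tsv", trait_table)
    cio.write_clusters_tsv(outdir / "clusters.tsv", clusters)

    truth = {
        "seed": seed,
        "genome_of": genome_of,
        "module_alternative_counts": {
            m[0].module_id: m[2] for m in modules
        },
        "planted_complements": planted_complements,
        "planted_seeds": planted_seeds,
        "planted_enrichments": [
            {"cluster": p.cluster, "trait": p.trait, "direction": p.direction}
            for p in planted_enr
        ],
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
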