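"""Readers and writers for the package's plain-text interchange formats.

All tabular inputs are TSV.  Metabolic networks are read either from a
reaction list (``reaction_id<TAB>substrates<TAB>products<TAB>reversible``,
``;``-joined compound lists, with an optional ``#compounds:`` header naming
the full compound universe so isolated compounds survive round trips) or
from a minimal SBML subset (species ids, reactant/product references and
the ``reversible`` attribute; SBML Level 2 and 3 accepted, everything else
ignored).  Co-occurrence networks come as edge-list TSV or GraphML.  The
annotated network is written as a CX2-style JSON document plus flat TSV
exports of node and edge annotation tables.
"""

from __future__ import annotations

import json
import re
import urllib.request
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .annotate import (
    COMPLEMENTARITY_KEY,
    COOCCURRENCE_KEY,
    CooccurrenceNetwork,
    TraitTable,
)
from .complementarity import PathwayComplement
from .enrichment import EnrichmentResult
from .kegg_modules import ModuleDefinition, parse_module_definition
from .seed_scores import CompoundMapping, MappingRow, SeedComplement, SeedScores
from .seeds import MetabolicNetwork, Reaction

__all__ = [
    "read_ko_table",
    "write_ko_table",
    "read_module_table",
    "write_module_table",
    "parse_kegg_flat_entry",
    "fetch_module_definition",
    "read_reaction_tsv",
    "write_reaction_tsv",
    "read_sbml",
    "read_compound_mapping",
    "write_compound_mapping",
    "read_network_tsv",
    "read_network_graphml",
    "read_node_taxonomy",
    "read_traits_tsv",
    "write_traits_tsv",
    "read_clusters_tsv",
    "write_clusters_tsv",
    "write_complements_tsv",
    "write_seed_score_matrices",
    "write_seed_complements_tsv",
    "write_enrichment_tsv",
    "write_cx2",
    "write_node_table",
    "write_edge_table",
]


def _rows(path: str | Path) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


# ---------------------------------------------------------------------------
# genomes and modules
# ---------------------------------------------------------------------------


def read_ko_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Genome → KO set from a two-column ``genome_id<TAB>KO`` table."""
    table: dict[str, set[str]] = {}
    for row in _rows(path):
        if len(row) < 2:
            raise ValueError(f"KO table row needs 2 columns, got {row!r}")
        table.setdefault(row[0], set()).add(row[1])
    return {g: frozenset(kos) for g, kos in table.items()}


def write_ko_table(path: str | Path, genomes: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for genome_id in sorted(genomes):
            for ko in sorted(genomes[genome_id]):
                fh.write(f"{genome_id}\t{ko}\n")


def read_module_table(path: str | Path) -> list[ModuleDefinition]:
    """Parse a ``module_id<TAB>definition[<TAB>name[<TAB>category]]`` table."""
    out = []
    for row in _rows(path):
        if len(row) < 2:
            raise ValueError(f"module table row needs >= 2 columns, got {row!r}")
        name = row[2] if len(row) > 2 else ""
        category = row[3] if len(row) > 3 else ""
        out.append(
            parse_module_definition(row[0], row[1], name=name, category=category)
        )
    return out


def write_module_table(
    path: str | Path, modules: Iterable[ModuleDefinition]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in modules:
            fh.write(f"{m.module_id}\t{m.normalized()}\t{m.name}\t{m.category}\n")


def parse_kegg_flat_entry(text: str) -> dict[str, str]:
    """Fields of a KEGG flat-file entry; multi-line DEFINITION fields are
    concatenated with a single space."""
    fields: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        if line.startswith("///"):
            break
        if line[:12].strip():
            current = line[:12].strip()
            fields.setdefault(current, []).append(line[12:].strip())
        elif current:
            fields[current].append(line[12:].strip())
    return {k: " ".join(v).strip() for k, v in fields.items()}


def fetch_module_definition(
    module_id: str, base_url: str = "https://rest.kegg.jp/get/"
) -> ModuleDefinition:
    """Fetch a module entry over KEGG REST and parse its DEFINITION field.

    Network access is opt-in (the CLI requires an explicit ``--fetch``
    flag); everything else in the package runs fully offline.
    """
    with urllib.request.urlopen(base_url + module_id, timeout=30) as resp:
        text = resp.read().decode("utf-8")
    fields = parse_kegg_flat_entry(text)
    if "DEFINITION" not in fields:
        raise ValueError(f"{module_id}: no DEFINITION field in KEGG entry")
    return parse_module_definition(
        module_id, fields["DEFINITION"], name=fields.get("NAME", "")
    )


# ---------------------------------------------------------------------------
# metabolic networks
# ---------------------------------------------------------------------------


def read_reaction_tsv(path: str | Path, network_id: str | None = None) -> MetabolicNetwork:
    """Reaction-list TSV → MetabolicNetwork.

    An optional leading ``#compounds: a;b;c`` comment enumerates the full
    compound universe (isolated compounds included); otherwise the universe
    is the union of all substrates and products.
    """
    path = Path(path)
    reactions: list[Reaction] = []
    declared: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*compounds:\s*(.*)$", line)
                if m and m.group(1).strip():
                    declared.update(c for c in m.group(1).split(";") if c)
                continue
            row = line.split("\t")
            if len(row) < 4:
                raise ValueError(f"reaction row needs 4 columns, got {row!r}")
            subs = frozenset(c for c in row[1].split(";") if c)
            prods = frozenset(c for c in row[2].split(";") if c)
            reactions.append(Reaction(row[0], subs, prods, row[3].strip() == "1"))
    compounds = set(declared)
    for rxn in reactions:
        compounds |= rxn.substrates | rxn.products
    return MetabolicNetwork(
        network_id=network_id or path.stem,
        compounds=frozenset(compounds),
        reactions=tuple(reactions),
    )


def write_reaction_tsv(path: str | Path, network: MetabolicNetwork) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#compounds: " + ";".join(sorted(network.compounds)) + "\n")
        for rxn in network.reactions:
            fh.write(
                f"{rxn.reaction_id}\t{';'.join(sorted(rxn.substrates))}\t"
                f"{';'.join(sorted(rxn.products))}\t{1 if rxn.reversible else 0}\n"
            )


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_sbml(path: str | Path, network_id: str | None = None) -> MetabolicNetwork:
    """Minimal SBML reader: species, reactions, reversibility; nothing else.

    Accepts the Level 2 and Level 3 dialects of ``listOfSpecies`` /
    ``listOfReactions``.  A missing ``reversible`` attribute defaults to
    true, the SBML Level 2 convention.
    """
    path = Path(path)
    tree = ET.parse(path)
    root = tree.getroot()
    species: set[str] = set()
    reactions: list[Reaction] = []
    for el in root.iter():
        if _local(el.tag) != "species":
            continue
        sid = el.get("id")
        if sid:
            species.add(sid)
    for el in root.iter():
        if _local(el.tag) != "reaction":
            continue
        rid = el.get("id") or f"rxn{len(reactions)}"
        reversible = el.get("reversible", "true").lower() == "true"
        subs: set[str] = set()
        prods: set[str] = set()
        for child in el:
            name = _local(child.tag)
            if name in ("listOfReactants", "listOfProducts"):
                bucket = subs if name == "listOfReactants" else prods
                for ref in child:
                    if _local(ref.tag) == "speciesReference":
                        sp = ref.get("species")
                        if sp:
                            bucket.add(sp)
        reactions.append(Reaction(rid, frozenset(subs), frozenset(prods), reversible))
    compounds = set(species)
    for rxn in reactions:
        compounds |= rxn.substrates | rxn.products
    return MetabolicNetwork(
        network_id=network_id or path.stem,
        compounds=frozenset(compounds),
        reactions=tuple(reactions),
    )


def read_compound_mapping(path: str | Path) -> CompoundMapping:
    """``internal_id<TAB>kegg_compound<TAB>kegg_maps(;)<TAB>module_linked``."""
    rows = []
    for row in _rows(path):
        if len(row) < 4:
            raise ValueError(f"mapping row needs 4 columns, got {row!r}")
        rows.append(
            MappingRow(
                internal_id=row[0],
                kegg_compound=row[1],
                kegg_maps=tuple(m for m in row[2].split(";") if m),
                module_linked=row[3].strip() == "1",
            )
        )
    return CompoundMapping(tuple(rows))


def write_compound_mapping(path: str | Path, mapping: CompoundMapping) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in mapping.rows:
            fh.write(
                f"{r.internal_id}\t{r.kegg_compound}\t{';'.join(r.kegg_maps)}\t"
                f"{1 if r.module_linked else 0}\n"
            )


# ---------------------------------------------------------------------------
# co-occurrence networks, traits, clusters
# ---------------------------------------------------------------------------


def read_network_tsv(
    path: str | Path, taxonomy: Mapping[str, str] | None = None
) -> CooccurrenceNetwork:
    """Edge-list TSV ``source<TAB>target<TAB>weight``.

    Node taxonomy defaults to the node id itself; supply a mapping (see
    :func:`read_node_taxonomy`) to override.
    """
    g = nx.Graph()
    for row in _rows(path):
        if len(row) < 2:
            raise ValueError(f"network row needs >= 2 columns, got {row!r}")
        weight = float(row[2]) if len(row) > 2 else 1.0
        g.add_edge(row[0], row[1], weight=weight)
    tax = {n: (taxonomy or {}).get(n, n) for n in g.nodes}
    return CooccurrenceNetwork(graph=g, taxonomy=tax)


def read_network_graphml(
    path: str | Path, taxonomy_key: str = "taxonomy"
) -> CooccurrenceNetwork:
    g_in = nx.read_graphml(path)
    g = nx.Graph()
    tax: dict[str, str] = {}
    for n, data in g_in.nodes(data=True):
        g.add_node(str(n))
        tax[str(n)] = str(data.get(taxonomy_key, n))
    for u, v, data in g_in.edges(data=True):
        g.add_edge(str(u), str(v), weight=float(data.get("weight", 1.0)))
    return CooccurrenceNetwork(graph=g, taxonomy=tax)


def read_node_taxonomy(path: str | Path) -> dict[str, str]:
    """``node_id<TAB>taxonomy`` table."""
    return {row[0]: row[1] for row in _rows(path)}


def read_genome_index(path: str | Path) -> dict[str, list[str]]:
    """``taxonomy<TAB>genome_id`` table; several genomes may share a taxonomy."""
    index: dict[str, list[str]] = {}
    for row in _rows(path):
        index.setdefault(row[0], []).append(row[1])
    return index


_TRAIT_TRUE = {"1", "true", "present", "yes"}
_TRAIT_FALSE = {"0", "false", "absent", "no"}
_TRAIT_UNKNOWN = {"", "na", "nan", "unknown", "none", "?"}


def read_traits_tsv(path: str | Path) -> TraitTable:
    """Long-format trait table.

    ``entity<TAB>trait<TAB>value[<TAB>score[<TAB>group]]`` where value is
    1/0/NA (synonyms accepted); NA means unknown, distinct from absent.
    """
    values: dict[str, dict[str, bool | None]] = {}
    groups: dict[str, str] = {}
    scores: dict[tuple[str, str], float] = {}
    for row in _rows(path):
        if len(row) < 3:
            raise ValueError(f"trait row needs >= 3 columns, got {row!r}")
        entity, trait, raw = row[0], row[1], row[2].strip().lower()
        if raw in _TRAIT_TRUE:
            val: bool | None = True
        elif raw in _TRAIT_FALSE:
            val = False
        elif raw in _TRAIT_UNKNOWN:
            val = None
        else:
            raise ValueError(f"unrecognized trait value {row[2]!r}")
        values.setdefault(entity, {})[trait] = val
        if len(row) > 3 and row[3].strip():
            scores[(entity, trait)] = float(row[3])
        if len(row) > 4 and row[4].strip():
            groups[trait] = row[4].strip()
    return TraitTable(values=values, groups=groups, scores=scores)


def write_traits_tsv(path: str | Path, traits: TraitTable) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entity in sorted(traits.values):
            for trait in sorted(traits.values[entity]):
                val = traits.values[entity][trait]
                raw = "NA" if val is None else ("1" if val else "0")
                score = traits.scores.get((entity, trait), "")
                group = traits.groups.get(trait, "other")
                fh.write(f"{entity}\t{trait}\t{raw}\t{score}\t{group}\n")


def read_clusters_tsv(path: str | Path) -> dict[str, str]:
    return {row[0]: row[1] for row in _rows(path)}


def write_clusters_tsv(path: str | Path, clusters: Mapping[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(clusters):
            fh.write(f"{node}\t{clusters[node]}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_complements_tsv(
    path: str | Path, complements: Iterable[PathwayComplement]
) -> None:
    """Edge-panel style table of pathway complements."""
    header = [
        "beneficiary",
        "donor",
        "module",
        "category",
        "missing_kos",
        "completed_alternative",
        "map_url",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for c in complements:
            fh.write(
                "\t".join(
                    [
                        c.beneficiary_id,
                        c.donor_id,
                        c.module_id,
                        c.category,
                        ";".join(sorted(c.missing_kos)),
                        ";".join(sorted(c.completed_alternative)),
                        c.map_url,
                    ]
                )
                + "\n"
            )


def write_seed_score_matrices(
    prefix: str | Path, scores: Iterable[SeedScores]
) -> tuple[Path, Path]:
    """Two beneficiary × donor matrices (complementarity, competition)."""
    scores = list(scores)
    benefs = sorted({s.beneficiary_id for s in scores})
    donors = sorted({s.donor_id for s in scores})
    lookup = {(s.beneficiary_id, s.donor_id): s for s in scores}
    paths = []
    for attr, suffix in (
        ("mi_complementarity", "complementarity"),
        ("mi_competition", "competition"),
    ):
        out = Path(f"{prefix}.{suffix}.tsv")
        with open(out, "w", encoding="utf-8") as fh:
            fh.write("beneficiary\\donor\t" + "\t".join(donors) + "\n")
            for b in benefs:
                cells = []
                for d in donors:
                    s = lookup.get((b, d))
                    cells.append("" if s is None else f"{getattr(s, attr):.6g}")
                fh.write(b + "\t" + "\t".join(cells) + "\n")
        paths.append(out)
    return paths[0], paths[1]


def write_seed_complements_tsv(
    path: str | Path, complements: Iterable[SeedComplement]
) -> None:
    """Long-format seed complement listing, one row per (pair, map, compound)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#beneficiary\tdonor\tkegg_map\tkegg_compound\tinternal_id\n")
        for sc in complements:
            kegg_to_internal = {kegg: internal for internal, kegg in sc.compounds}
            for map_id in sorted(sc.kegg_maps):
                for kegg in sorted(sc.kegg_maps[map_id]):
                    fh.write(
                        f"{sc.beneficiary_id}\t{sc.donor_id}\t{map_id}\t"
                        f"{kegg}\t{kegg_to_internal.get(kegg, '')}\n"
                    )


def write_enrichment_tsv(
    path: str | Path, results: Iterable[EnrichmentResult]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#cluster\ttrait\tdirection\tk\tn\tK\tN\tp_value\tq_value\n")
        for r in results:
            fh.write(
                f"{r.cluster}\t{r.trait}\t{r.direction}\t{r.k}\t{r.n}\t"
                f"{r.K}\t{r.N}\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )


# ---------------------------------------------------------------------------
# CX2 and annotation-table exports
# ---------------------------------------------------------------------------


def _edge_attr_json(data: Mapping) -> dict[str, str]:
    """Complement sub-tables serialized as JSON strings for CX2/TSV."""
    out: dict[str, str] = {}
    if data.get("pathway_complements"):
        out["pathway_complements"] = json.dumps(
            {
                pair: [
                    {
                        "module": c.module_id,
                        "module_name": c.module_name,
                        "category": c.category,
                        "missing_kos": sorted(c.missing_kos),
                        "completed_alternative": sorted(c.completed_alternative),
                        "map_url": c.map_url,
                    }
                    for c in table
                ]
                for pair, table in sorted(data["pathway_complements"].items())
            },
            sort_keys=True,
        )
    if data.get("seed_scores"):
        out["seed_scores"] = json.dumps(
            {
                pair: {
                    "mi_complementarity": s.mi_complementarity,
                    "mi_competition": s.mi_competition,
                }
                for pair, s in sorted(data["seed_scores"].items())
            },
            sort_keys=True,
        )
    if data.get("seed_complements"):
        out["seed_complements"] = json.dumps(
            {
                pair: {
                    "compounds": [list(c) for c in sc.compounds],
                    "kegg_maps": {m: sorted(v) for m, v in sc.kegg_maps.items()},
                }
                for pair, sc in sorted(data["seed_complements"].items())
            },
            sort_keys=True,
        )
    return out


def write_cx2(path: str | Path, annotated: nx.MultiDiGraph, name: str = "crossnet") -> None:
    """Write the annotated network as a CX2-style JSON document.

    Aspects: ``CXVersion``, ``networkAttributes``, ``attributeDeclarations``,
    ``nodes``, ``edges``, ``status``.  Node attributes: taxonomy, genomes,
    cluster, one boolean-or-null column per trait.  Edge attributes:
    interaction type, weight/sign for co-occurrence edges, JSON-serialized
    complement sub-tables for complementarity edges.
    """
    node_ids = {n: i for i, n in enumerate(sorted(annotated.nodes))}
    traits: set[str] = set()
    for _, data in annotated.nodes(data=True):
        traits.update(data.get("traits", {}))
    nodes_aspect = []
    for n in sorted(annotated.nodes):
        data = annotated.nodes[n]
        v: dict = {"name": n, "taxonomy": data.get("taxonomy", "")}
        v["genomes"] = ";".join(data.get("genomes", []))
        if "cluster" in data:
            v["cluster"] = str(data["cluster"])
        for t in sorted(traits):
            val = data.get("traits", {}).get(t)
            v[f"trait::{t}"] = "" if val is None else str(bool(val)).lower()
        nodes_aspect.append({"id": node_ids[n], "v": v})
    edges_aspect = []
    eid = 0
    for u, v_, key, data in sorted(
        annotated.edges(keys=True, data=True), key=lambda e: (e[0], e[1], e[2])
    ):
        attrs: dict = {"interaction_type": data.get("interaction_type", "")}
        if key == COOCCURRENCE_KEY:
            attrs["weight"] = data.get("weight", 1.0)
            attrs["sign"] = data.get("sign", "")
        elif key == COMPLEMENTARITY_KEY:
            attrs["donor"] = data.get("donor", u)
            attrs["beneficiary"] = data.get("beneficiary", v_)
            attrs.update(_edge_attr_json(data))
        edges_aspect.append(
            {"id": eid, "s": node_ids[u], "t": node_ids[v_], "v": attrs}
        )
        eid += 1
    doc = [
        {"CXVersion": "2.0", "hasFragments": False},
        {"networkAttributes": [{"name": name}]},
        {
            "attributeDeclarations": [
                {
                    "nodes": {
                        "name": {"d": "string"},
                        "taxonomy": {"d": "string"},
                        "genomes": {"d": "string"},
                        "cluster": {"d": "string"},
                        **{f"trait::{t}": {"d": "string"} for t in sorted(traits)},
                    },
                    "edges": {
                        "interaction_type": {"d": "string"},
                        "weight": {"d": "double"},
                        "sign": {"d": "string"},
                        "donor": {"d": "string"},
                        "beneficiary": {"d": "string"},
                        "pathway_complements": {"d": "string"},
                        "seed_scores": {"d": "string"},
                        "seed_complements": {"d": "string"},
                    },
                }
            ]
        },
        {"nodes": nodes_aspect},
        {"edges": edges_aspect},
        {"status": [{"error": "", "success": True}]},
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def write_node_table(path: str | Path, annotated: nx.MultiDiGraph) -> None:
    traits: set[str] = set()
    for _, data in annotated.nodes(data=True):
        traits.update(data.get("traits", {}))
    cols = ["node", "taxonomy", "genomes", "cluster"] + [
        f"trait::{t}" for t in sorted(traits)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for n in sorted(annotated.nodes):
            data = annotated.nodes[n]
            row = [
                n,
                data.get("taxonomy", ""),
                ";".join(data.get("genomes", [])),
                str(data.get("cluster", "")),
            ]
            for t in sorted(traits):
                val = data.get("traits", {}).get(t)
                row.append("" if val is None else ("1" if val else "0"))
            fh.write("\t".join(row) + "\n")


def write_edge_table(path: str | Path, annotated: nx.MultiDiGraph) -> None:
    cols = [
        "source",
        "target",
        "interaction_type",
        "weight",
        "sign",
        "pathway_complements",
        "seed_scores",
        "seed_complements",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for u, v, key, data in sorted(
            annotated.edges(keys=True, data=True), key=lambda e: (e[0], e[1], e[2])
        ):
            serialized = _edge_attr_json(data)
            fh.write(
                "\t".join(
                    [
                        u,
                        v,
                        data.get("interaction_type", ""),
                        str(data.get("weight", "")),
                        data.get("sign", ""),
                        serialized.get("pathway_complements", ""),
                        serialized.get("seed_scores", ""),
                        serialized.get("seed_complements", ""),
                    ]
                )
                + "\n"
            )
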