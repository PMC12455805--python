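"""Network annotation: conservation, directed complementarity edges, filters."""

from __future__ import annotations

import networkx as nx
import pytest

from crossnet.annotate import (
    COMPLEMENTARITY_KEY,
    COOCCURRENCE_KEY,
    CooccurrenceNetwork,
    TraitTable,
    annotate_network,
    filter_nodes_by_traits,
)
from crossnet.complementarity import PathwayComplement
from crossnet.seed_scores import SeedScores


def complement(beneficiary, donor, module="M00001", missing=("K00001",)):
    return PathwayComplement(
        beneficiary_id=beneficiary,
        donor_id=donor,
        module_id=module,
        module_name="",
        category="",
        missing_kos=frozenset(missing),
        completed_alternative=frozenset(missing) | {"K09999"},
        map_url="",
    )


@pytest.fixture()
def simple_network():
    g = nx.Graph()
    g.add_edge("t1", "t2", weight=0.8)
    g.add_edge("t2", "t3", weight=-0.4)
    return CooccurrenceNetwork(
        graph=g, taxonomy={"t1": "s one", "t2": "s two", "t3": "s three"}
    )


class TestNetworkValidation:
    def test_self_edge_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "a")
        with pytest.raises(ValueError, match="self-edge"):
            CooccurrenceNetwork(graph=g)

    def test_nonfinite_weight_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=float("inf"))
        with pytest.raises(ValueError, match="non-finite"):
            CooccurrenceNetwork(graph=g)


class TestAnnotateNetwork:
    def test_conservation_of_nodes_and_edges(self, simple_network):
        node_genomes = {"t1": ["G1"], "t2": ["G2"], "t3": []}
        annotated = annotate_network(
            simple_network,
            node_genomes,
            pathway_complements=[complement("G2", "G1")],
        )
        assert set(annotated.nodes) == set(simple_network.graph.nodes)
        cooc = [
            (u, v, d["weight"])
            for u, v, k, d in annotated.edges(keys=True, data=True)
            if k == COOCCURRENCE_KEY
        ]
        assert {frozenset((u, v)) for u, v, _ in cooc} == {
            frozenset(e[:2]) for e in simple_network.graph.edges
        }
        weights = {frozenset((u, v)): w for u, v, w in cooc}
        assert weights[frozenset(("t1", "t2"))] == 0.8
        assert weights[frozenset(("t2", "t3"))] == -0.4

    def test_sign_attribute_convention(self, simple_network):
        annotated = annotate_network(simple_network, {})
        signs = {
            frozenset((u, v)): d["sign"]
            for u, v, k, d in annotated.edges(keys=True, data=True)
            if k == COOCCURRENCE_KEY
        }
        assert signs[frozenset(("t1", "t2"))] == "positive co-occurrence"
        assert signs[frozenset(("t2", "t3"))] == "mutual exclusion"

    def test_two_directed_edges_for_mutual_complements(self, simple_network):
        node_genomes = {"t1": ["G1"], "t2": ["G2"], "t3": []}
        annotated = annotate_network(
            simple_network,
            node_genomes,
            pathway_complements=[
                complement("G2", "G1"),
                complement("G1", "G2"),
            ],
        )
        comp = [
            (u, v, d)
            for u, v, k, d in annotated.edges(keys=True, data=True)
            if k == COMPLEMENTARITY_KEY
        ]
        assert {(u, v) for u, v, _ in comp} == {("t1", "t2"), ("t2", "t1")}
        for u, v, d in comp:
            assert d["donor"] == u and d["beneficiary"] == v

    def test_no_complements_only_node_attributes(self, simple_network):
        annotated = annotate_network(simple_network, {"t1": ["G1"]})
        assert all(
            k == COOCCURRENCE_KEY for _, _, k in annotated.edges(keys=True)
        )

    def test_genome_combination_subtables(self, simple_network):
        node_genomes = {"t1": ["G1a", "G1b"], "t2": ["G2a", "G2b", "G2c"], "t3": []}
        complements = [
            complement(gb, gd)
            for gd in ("G1a", "G1b")
            for gb in ("G2a", "G2b", "G2c")
        ]
        annotated = annotate_network(
            simple_network, node_genomes, pathway_complements=complements
        )
        data = annotated.get_edge_data("t1", "t2", COMPLEMENTARITY_KEY)
        assert len(data["pathway_complements"]) == 6  # 2 x 3 ordered combos

    def test_unmapped_genome_in_complement_raises(self, simple_network):
        with pytest.raises(ValueError, match="unmapped genome"):
            annotate_network(
                simple_network,
                {"t1": ["G1"]},
                pathway_complements=[complement("GX", "G1")],
            )

    def test_idempotent_on_reannotation(self, simple_network):
        node_genomes = {"t1": ["G1"], "t2": ["G2"], "t3": []}
        kwargs = dict(
            node_genomes=node_genomes,
            pathway_complements=[complement("G2", "G1")],
            seed_scores=[SeedScores("G2", "G1", 0.5, 0.2)],
        )
        once = annotate_network(simple_network, **kwargs)
        twice = annotate_network(once, **kwargs)
        assert set(once.edges(keys=True)) == set(twice.edges(keys=True))
        assert set(once.nodes) == set(twice.nodes)


class TestTraitFilter:
    @pytest.fixture()
    def annotated_with_traits(self, simple_network):
        traits = TraitTable(
            values={
                "G1": {"aerobe": True, "halophile": False, "butanol": None},
                "G2": {"aerobe": True, "halophile": True, "butanol": None},
            },
            groups={
                "aerobe": "lifestyle",
                "halophile": "lifestyle",
                "butanol": "metabolite",
            },
        )
        return annotate_network(
            simple_network, {"t1": ["G1"], "t2": ["G2"], "t3": []}, traits=traits
        )

    def test_empty_selection_any_is_empty(self, annotated_with_traits):
        assert filter_nodes_by_traits(annotated_with_traits, [], "ANY") == set()

    def test_single_trait(self, annotated_with_traits):
        assert filter_nodes_by_traits(annotated_with_traits, ["aerobe"]) == {
            "t1",
            "t2",
        }

    def test_all_mode_requires_every_trait(self, annotated_with_traits):
        got = filter_nodes_by_traits(
            annotated_with_traits, ["aerobe", "halophile"], "ALL"
        )
        assert got == {"t2"}

    def test_unknown_counts_as_not_present(self, annotated_with_traits):
        assert filter_nodes_by_traits(annotated_with_traits, ["butanol"]) == set()

    def test_undeclared_trait_raises(self, annotated_with_traits):
        with pytest.raises(ValueError, match="undeclared trait"):
            filter_nodes_by_traits(annotated_with_traits, ["swims"])

    def test_matches_naive_per_node_scan(self, rng, simple_network):
        trait_names = [f"t{i}" for i in range(6)]
        values = {
            g: {
                t: [True, False, None][int(rng.integers(3))]
                for t in trait_names
            }
            for g in ("G1", "G2", "G3")
        }
        traits = TraitTable(values=values)
        annotated = annotate_network(
            simple_network,
            {"t1": ["G1"], "t2": ["G2"], "t3": ["G3"]},
            traits=traits,
        )
        chosen = trait_names[:3]
        for mode in ("ANY", "ALL"):
            got = filter_nodes_by_traits(annotated, chosen, mode)
            expected = set()
            for n, data in annotated.nodes(data=True):
                flags = [data["traits"].get(t) is True for t in chosen]
                if (mode == "ANY" and any(flags)) or (
                    mode == "ALL" and all(flags)
                ):
                    expected.add(n)
            assert got == expected
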