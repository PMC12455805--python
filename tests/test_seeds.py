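"""Seed sets: compound graph, SCC condensation, seed extraction."""

from __future__ import annotations

import networkx as nx
import pytest
from oracles import edge_set_oracle, reachable_from, scc_partition_oracle

from crossnet.fixtures import gen_metabolic_network, gen_random_scc_spec
from crossnet.seeds import (
    MetabolicNetwork,
    Reaction,
    build_compound_graph,
    compute_seed_set,
    condense_sccs,
    normalize_network,
)


def net(reactions, compounds=None, network_id="N"):
    if compounds is None:
        compounds = set()
        for r in reactions:
            compounds |= r.substrates | r.products
    return MetabolicNetwork(network_id, frozenset(compounds), tuple(reactions))


class TestCompoundGraph:
    def test_irreversible_reaction_edges(self):
        g = build_compound_graph(
            net([Reaction("r1", frozenset({"A", "B"}), frozenset({"C"}))])
        )
        assert set(g.edges) == {("A", "C"), ("B", "C")}

    def test_reversible_reaction_edges_both_ways(self):
        g = build_compound_graph(
            net([Reaction("r1", frozenset({"A"}), frozenset({"B"}), True)])
        )
        assert set(g.edges) == {("A", "B"), ("B", "A")}

    def test_self_edge_dropped(self):
        g = build_compound_graph(
            net([Reaction("r1", frozenset({"A"}), frozenset({"A", "B"}))])
        )
        assert set(g.edges) == {("A", "B")}

    def test_unknown_compound_rejected(self):
        with pytest.raises(ValueError, match="unknown compounds"):
            MetabolicNetwork(
                "N",
                frozenset({"A"}),
                (Reaction("r1", frozenset({"A"}), frozenset({"B"})),),
            )

    def test_duplicate_reaction_id_rejected(self):
        r = Reaction("r1", frozenset({"A"}), frozenset({"B"}))
        with pytest.raises(ValueError, match="duplicate"):
            MetabolicNetwork("N", frozenset({"A", "B"}), (r, r))

    def test_random_network_matches_per_reaction_oracle(self, rng):
        compounds = [f"C{i:03d}" for i in range(30)]
        reactions = []
        for i in range(50):
            subs = frozenset(rng.choice(compounds, size=rng.integers(1, 4), replace=False))
            prods = frozenset(rng.choice(compounds, size=rng.integers(1, 4), replace=False))
            reactions.append(Reaction(f"r{i}", subs, prods, bool(rng.random() < 0.4)))
        network = net(reactions, compounds)
        g = build_compound_graph(network)
        assert set(g.edges) == edge_set_oracle(reactions)


class TestCondensation:
    def test_dag_every_node_own_scc(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        scc_of, cond = condense_sccs(g)
        assert len(set(scc_of.values())) == 3
        assert nx.is_directed_acyclic_graph(cond)

    def test_two_cycle_single_scc(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        scc_of, _ = condense_sccs(g)
        assert scc_of["A"] == scc_of["B"]

    def test_random_digraph_matches_reachability_oracle(self, rng):
        nodes = [f"n{i}" for i in range(60)]
        edges = [
            (u, v)
            for u in nodes
            for v in nodes
            if u != v and rng.random() < 0.04
        ]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        scc_of, _ = condense_sccs(g)
        oracle = scc_partition_oracle(nodes, edges)
        # same partition: same grouping of nodes
        def groups(mapping):
            inv = {}
            for n, c in mapping.items():
                inv.setdefault(c, set()).add(n)
            return {frozenset(v) for v in inv.values()}

        assert groups(scc_of) == groups(oracle)


class TestSeedSet:
    def test_chain_seed_is_the_source(self):
        s = compute_seed_set(
            net([
                Reaction("r1", frozenset({"A"}), frozenset({"B"})),
                Reaction("r2", frozenset({"B"}), frozenset({"C"})),
            ])
        )
        assert dict(s.seeds) == {"A": 1.0}
        assert s.non_seeds == {"B", "C"}

    def test_isolated_reversible_pair_splits_confidence(self):
        s = compute_seed_set(
            net([Reaction("r1", frozenset({"A"}), frozenset({"B"}), True)])
        )
        assert dict(s.seeds) == {"A": 0.5, "B": 0.5}

    def test_isolated_compound_is_seed_with_full_confidence(self):
        s = compute_seed_set(
            net(
                [Reaction("r1", frozenset({"A"}), frozenset({"B"}))],
                compounds={"A", "B", "Z"},
            )
        )
        assert s.seeds["Z"] == 1.0

    def test_empty_network_raises(self):
        with pytest.raises(ValueError, match="no compounds"):
            compute_seed_set(MetabolicNetwork("N", frozenset(), ()))

    def test_planted_structure_recovered(self, rng):
        for _ in range(30):
            sizes, edges = gen_random_scc_spec(rng)
            network, planted = gen_metabolic_network(sizes, edges, rng=rng)
            s = compute_seed_set(network)
            assert dict(s.seeds) == pytest.approx(planted)
            assert s.non_seeds == network.compounds - set(planted)

    def test_reachability_closure_and_confidence_normalization(self, rng):
        sizes, edges = gen_random_scc_spec(rng)
        network, _ = gen_metabolic_network(sizes, edges, rng=rng)
        s = compute_seed_set(network)
        g = build_compound_graph(network)
        adj = {n: set(g.successors(n)) for n in g.nodes}
        reachable = set()
        for seed in s.seeds:
            reachable |= reachable_from(adj, seed)
        assert reachable == network.compounds
        # per source SCC: equal confidences summing to 1
        by_scc = {}
        for c, conf in s.seeds.items():
            by_scc.setdefault(s.scc_of[c], []).append(conf)
        for confs in by_scc.values():
            assert len(set(confs)) == 1
            assert sum(confs) == pytest.approx(1.0)

    def test_marking_reactions_reversible_never_adds_sccs(self, rng):
        sizes, edges = gen_random_scc_spec(rng)
        network, _ = gen_metabolic_network(
            sizes, edges, reversible_fraction=0.0, rng=rng
        )
        all_rev = MetabolicNetwork(
            network.network_id,
            network.compounds,
            tuple(
                Reaction(r.reaction_id, r.substrates, r.products, True)
                for r in network.reactions
            ),
        )
        n_scc = len(set(compute_seed_set(network).scc_of.values()))
        n_scc_rev = len(set(compute_seed_set(all_rev).scc_of.values()))
        assert n_scc_rev <= n_scc


class TestNormalization:
    def test_compartment_suffix_stripped(self):
        network = net(
            [
                Reaction("r1", frozenset({"cpd00001_c0"}), frozenset({"cpd00002_c0"})),
                Reaction("r2", frozenset({"cpd00002_e0"}), frozenset({"cpd00003_c0"})),
            ]
        )
        fixed = normalize_network(network)
        assert fixed.compounds == {"cpd00001", "cpd00002", "cpd00003"}
        # compartments merged: the chain is now connected through cpd00002
        s = compute_seed_set(network)
        assert dict(s.seeds) == {"cpd00001": 1.0}

    def test_pseudo_reactions_dropped(self):
        network = net(
            [
                Reaction("bio1", frozenset({"A"}), frozenset({"B"})),
                Reaction("EX_cpd1", frozenset({"A"}), frozenset({"C"})),
                Reaction("r1", frozenset({"A"}), frozenset({"B"})),
            ]
        )
        fixed = normalize_network(network)
        assert [r.reaction_id for r in fixed.reactions] == ["r1"]
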