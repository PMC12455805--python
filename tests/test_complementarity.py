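"""Pathway complementarity: complement search, dedup, map URLs."""

from __future__ import annotations

from oracles import complements_oracle, unique_pairs_oracle

from crossnet.complementarity import (
    BENEFICIARY_COLOR,
    DONOR_COLOR,
    GenomeAnnotation,
    find_pathway_complements,
    kegg_map_color_url,
    minimal_complements,
    unique_complements,
)
from crossnet.fixtures import gen_genome_pair, gen_module_definition
from crossnet.kegg_modules import enumerate_alternatives, parse_module_definition


def module_with_alts(raw, module_id="MX"):
    d = parse_module_definition(module_id, raw)
    return d, enumerate_alternatives(d)


class TestComplementSearch:
    def test_shared_required_ko_is_the_complement(self):
        # serine-biosynthesis-style module: every alternative needs K00831
        d, alts = module_with_alts("(K00058,K00831) K00831 (K01079,K02203)")
        assert all("K00831" in a.ko_set for a in alts)
        target = min(alts, key=lambda a: sorted(a.ko_set))
        beneficiary = GenomeAnnotation("B", target.ko_set - {"K00831"})
        donor = GenomeAnnotation("D", frozenset({"K00831"}))
        found = find_pathway_complements(beneficiary, donor, [(d, alts)])
        assert found and all(c.missing_kos == {"K00831"} for c in found)

    def test_single_missing_ko_trehalose_style(self):
        # beneficiary one starch-synthase-like KO short of the alternative
        d, alts = module_with_alts("K00963 (K00703,K16153) K01214")
        alt = next(a for a in alts if "K00703" in a.ko_set)
        beneficiary = GenomeAnnotation("B", alt.ko_set - {"K00703"})
        donor = GenomeAnnotation("D", frozenset({"K00703"}))
        found = find_pathway_complements(beneficiary, donor, [(d, alts)])
        assert {c.missing_kos for c in found} == {frozenset({"K00703"})}

    def test_complete_beneficiary_yields_nothing(self):
        d, alts = module_with_alts("(K00001,K00002) K00003")
        beneficiary = GenomeAnnotation("B", d.kos())
        donor = GenomeAnnotation("D", d.kos())
        assert find_pathway_complements(beneficiary, donor, [(d, alts)]) == []

    def test_identical_genomes_yield_nothing(self):
        d, alts = module_with_alts("(K00001,K00002) K00003")
        g = GenomeAnnotation("A", frozenset({"K00001"}))
        assert find_pathway_complements(g, g, [(d, alts)]) == []

    def test_empty_donor_yields_nothing(self):
        d, alts = module_with_alts("K00001 K00002")
        beneficiary = GenomeAnnotation("B", frozenset({"K00001"}))
        donor = GenomeAnnotation("D", frozenset())
        assert find_pathway_complements(beneficiary, donor, [(d, alts)]) == []

    def test_matches_set_condition_oracle_on_random_pairs(self, rng):
        modules = []
        for i in range(5):
            raw, _ = gen_module_definition(
                rng, module_id=f"M{i:05d}", ko_start=1 + i * 500
            )
            modules.append(module_with_alts(raw, f"M{i:05d}"))
        universe = sorted(set().union(*(d.kos() for d, _ in modules)))
        for trial in range(20):
            bkos = frozenset(k for k in universe if rng.random() < 0.6)
            dkos = frozenset(k for k in universe if rng.random() < 0.6)
            got = find_pathway_complements(
                GenomeAnnotation("B", bkos), GenomeAnnotation("D", dkos), modules
            )
            got_pairs = {(c.module_id, c.missing_kos) for c in got}
            expected = complements_oracle(
                bkos,
                dkos,
                {d.module_id: [a.ko_set for a in alts] for d, alts in modules},
            )
            assert got_pairs == expected

    def test_emitted_records_satisfy_set_invariants(self, rng):
        raw, _ = gen_module_definition(rng, options_per_step=[2, 3, 2])
        d, alts = module_with_alts(raw)
        alt = alts[0]
        bkos, dkos = gen_genome_pair(alt, 2, rng)
        found = find_pathway_complements(
            GenomeAnnotation("B", bkos), GenomeAnnotation("D", dkos), [(d, alts)]
        )
        assert found
        for c in found:
            assert c.missing_kos
            assert not c.missing_kos & bkos
            assert c.missing_kos <= dkos
            assert c.completed_alternative <= bkos | c.missing_kos

    def test_max_missing_monotonicity(self, rng):
        raw, _ = gen_module_definition(rng, options_per_step=[3, 3, 2])
        d, alts = module_with_alts(raw)
        alt = alts[0]
        bkos, dkos = gen_genome_pair(alt, min(4, len(alt.ko_set)), rng)
        donor = GenomeAnnotation("D", dkos | d.kos())
        beneficiary = GenomeAnnotation("B", bkos)
        unbounded = find_pathway_complements(beneficiary, donor, [(d, alts)])
        capped = find_pathway_complements(
            beneficiary, donor, [(d, alts)], max_missing=4
        )
        assert len(unique_complements(capped)) <= len(unique_complements(unbounded))
        assert all(len(c.missing_kos) <= 4 for c in capped)

    def test_minimal_only_drops_strict_supersets(self):
        d, alts = module_with_alts("(K00001,K00001+K00002) K00003")
        beneficiary = GenomeAnnotation("B", frozenset())
        donor = GenomeAnnotation("D", frozenset({"K00001", "K00002", "K00003"}))
        found = find_pathway_complements(beneficiary, donor, [(d, alts)])
        kept = minimal_complements(found)
        assert {frozenset(c.missing_kos) for c in kept} == {
            frozenset({"K00001", "K00003"})
        }


class TestUniqueComplements:
    def test_same_module_and_missing_collapse(self):
        d, alts = module_with_alts("(K00001,K00002) (K00003,K00004)")
        beneficiary = GenomeAnnotation("B", frozenset({"K00001"}))
        donor = GenomeAnnotation("D", d.kos())
        found = find_pathway_complements(beneficiary, donor, [(d, alts)])
        uniq = unique_complements(found)
        assert sum(uniq.values()) == len(found)
        assert len(uniq) <= len(found)

    def test_empty_input(self):
        assert unique_complements([]) == {}

    def test_count_matches_quadratic_oracle(self, rng):
        modules = []
        for i in range(3):
            raw, _ = gen_module_definition(
                rng, module_id=f"M{i:05d}", ko_start=1 + i * 500
            )
            modules.append(module_with_alts(raw, f"M{i:05d}"))
        universe = sorted(set().union(*(d.kos() for d, _ in modules)))
        records = []
        for _ in range(10):
            bkos = frozenset(k for k in universe if rng.random() < 0.5)
            dkos = frozenset(k for k in universe if rng.random() < 0.7)
            records.extend(
                find_pathway_complements(
                    GenomeAnnotation("B", bkos),
                    GenomeAnnotation("D", dkos),
                    modules,
                )
            )
        got = len(unique_complements(records))
        assert got == unique_pairs_oracle(
            [(c.module_id, c.missing_kos) for c in records]
        )


class TestMapUrl:
    def test_empty_sets_url_has_only_map_id(self):
        url = kegg_map_color_url("map00260", set(), set())
        assert url.endswith("map00260")

    def test_colors_and_sorting(self):
        url = kegg_map_color_url("map00260", {"K00002"}, {"K00001"})
        assert f"K00001%09{DONOR_COLOR}" in url
        assert f"K00002%09{BENEFICIARY_COLOR}" in url
        assert url.index("K00001") < url.index("K00002")

    def test_deterministic(self):
        a = kegg_map_color_url("M00002", {"K00003", "K00001"}, {"K00002"})
        b = kegg_map_color_url("M00002", {"K00001", "K00003"}, {"K00002"})
        assert a == b
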