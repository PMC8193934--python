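import pytest

from netpharm.errors import EmptyResultError
from netpharm.geneset_ops import GeneSet
from netpharm.hit_network import (
    build_hit,
    per_herb_target_partition,
    representative_components,
)
from netpharm.screening import ActiveComponentSet


def _acs(mapping):
    return ActiveComponentSet(targets_by_herb={
        herb: {mol: frozenset(genes) for mol, genes in mols.items()}
        for herb, mols in mapping.items()
    })


def _genes(*symbols):
    return GeneSet(name="putative", symbols=frozenset(symbols))


class TestBuildHit:
    def test_shared_ingredient_single_node(self):
        active = _acs({"H1": {"Q": {"TNF"}}, "H2": {"Q": {"TNF"}}})
        net = build_hit(active, _genes("TNF"))
        assert net.ingredients == {"Q"}
        assert net.herbs == {"H1", "H2"}
        assert net.genes == {"TNF"}
        # one ingredient node, two herb edges, one gene edge
        assert net.graph.number_of_edges() == 3

    def test_out_of_intersection_ingredient_absent(self):
        active = _acs({"H1": {"A": {"TNF"}, "B": {"TP53"}}})
        net = build_hit(active, _genes("TNF"))
        assert net.ingredients == {"A"}
        assert "TP53" not in net.genes

    def test_no_surviving_ingredient_is_fatal(self):
        active = _acs({"H1": {"A": {"TP53"}}})
        with pytest.raises(EmptyResultError):
            build_hit(active, _genes("TNF"))

    def test_gene_degree_equals_restricted_target_count(self, bundle):
        from netpharm.screening import map_targets, screen_ingredients

        active = screen_ingredients(bundle.ingredients)
        components = map_targets(active, bundle.target_map, bundle.symbol_map)
        putative = GeneSet("putative", frozenset(bundle.ledger.intersection))
        net = build_hit(components, putative)
        merged: dict[str, set[str]] = {}
        for mols in components.targets_by_herb.values():
            for mol, genes in mols.items():
                merged.setdefault(mol, set()).update(
                    genes & putative.symbols
                )
        for mol in net.ingredients:
            assert net.gene_degree(mol) == len(merged[mol])

    def test_planted_tripartite_counts(self, bundle):
        from netpharm.screening import map_targets, screen_ingredients

        active = screen_ingredients(bundle.ingredients)
        components = map_targets(active, bundle.target_map, bundle.symbol_map)
        putative = GeneSet("putative", frozenset(bundle.ledger.intersection))
        net = build_hit(components, putative)
        assert len(net.herbs) == 10
        assert len(net.genes) == len(bundle.ledger.intersection)
        # every screened compound targets >= 3 genes of a 300-gene union of
        # which 200 are putative, so all survive the restriction
        assert net.ingredients <= {m for _, m in bundle.ledger.ingredients.pass_keys}


class TestPerHerbPartition:
    def test_simple_partition(self):
        active = _acs({"H1": {"M1": {"A", "B"}}, "H2": {"M2": {"B"}}})
        net = build_hit(active, _genes("A", "B"))
        assert per_herb_target_partition(net) == {
            "H1": {"A", "B"},
            "H2": {"B"},
        }

    def test_fully_shared_components_give_identical_sets(self):
        active = _acs({
            "H1": {"Q": {"A", "B"}},
            "H2": {"Q": {"A", "B"}},
        })
        net = build_hit(active, _genes("A", "B"))
        parts = per_herb_target_partition(net)
        assert parts["H1"] == parts["H2"] == {"A", "B"}


class TestRepresentatives:
    def test_argmax_by_degree(self):
        active = _acs({"H1": {"M1": {"A", "B", "C"}, "M2": {"A"}}})
        net = build_hit(active, _genes("A", "B", "C"))
        hubs = _genes("A", "B", "C")
        assert representative_components(net, hubs) == {"H1": "M1"}

    def test_tie_breaks_lexicographically(self):
        active = _acs({"H1": {"M2": {"A", "B"}, "M1": {"A", "C"}}})
        net = build_hit(active, _genes("A", "B", "C"))
        hubs = _genes("A", "B", "C")
        assert representative_components(net, hubs) == {"H1": "M1"}

    def test_herb_without_hub_target_omitted(self):
        active = _acs({"H1": {"M1": {"A"}}, "H2": {"M2": {"B"}}})
        net = build_hit(active, _genes("A", "B"))
        chosen = representative_components(net, _genes("A"))
        assert chosen == {"H1": "M1"}

    def test_matches_bruteforce_recount(self, bundle):
        from netpharm.screening import map_targets, screen_ingredients

        active = screen_ingredients(bundle.ingredients)
        components = map_targets(active, bundle.target_map, bundle.symbol_map)
        putative = GeneSet("putative", frozenset(bundle.ledger.intersection))
        net = build_hit(components, putative)
        hubs = GeneSet("hubs", frozenset(bundle.ledger.ppi.module_nodes))
        chosen = representative_components(net, hubs)

        # independent recount straight from the component mapping
        merged: dict[str, set[str]] = {}
        herbs_of: dict[str, set[str]] = {}
        for herb, mols in components.targets_by_herb.items():
            for mol, genes in mols.items():
                merged.setdefault(mol, set()).update(genes & putative.symbols)
                herbs_of.setdefault(mol, set()).add(herb)
        for herb, mol in chosen.items():
            degree = len(merged[mol] & hubs.symbols)
            rivals = [
                m for m, hs in herbs_of.items()
                if herb in hs and merged[m]  # in the HIT network
            ]
            best = max(len(merged[m] & hubs.symbols) for m in rivals)
            assert degree == best > 0
            ties = sorted(
                m for m in rivals if len(merged[m] & hubs.symbols) == best
            )
            assert mol == ties[0]
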