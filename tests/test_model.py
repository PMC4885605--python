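"""Network model construction, complexes, coverage, projections, JSON."""

import pytest

from regnet import (
    Effect,
    Evidence,
    GeneNode,
    Interaction,
    RawInteractionError,
    RegulatoryNetwork,
    SchemaError,
    add_interactions,
    collapse_complexes,
    effect_join,
    evidence_join,
    from_json,
    genomic_coverage,
    project_subnetwork,
    to_json,
)
from conftest import make_network


class TestLattices:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (Effect.ACTIVATION, Effect.ACTIVATION, Effect.ACTIVATION),
            (Effect.ACTIVATION, Effect.REPRESSION, Effect.DUAL),
            (Effect.UNKNOWN, Effect.REPRESSION, Effect.REPRESSION),
            (Effect.DUAL, Effect.ACTIVATION, Effect.DUAL),
            (Effect.UNKNOWN, Effect.UNKNOWN, Effect.UNKNOWN),
        ],
    )
    def test_effect_join(self, a, b, expected):
        assert effect_join(a, b) == expected
        assert effect_join(b, a) == expected

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (Evidence.WEAK, Evidence.STRONG, Evidence.STRONG),
            (Evidence.UNKNOWN, Evidence.WEAK, Evidence.WEAK),
            (Evidence.WEAK, Evidence.WEAK, Evidence.WEAK),
        ],
    )
    def test_evidence_join(self, a, b, expected):
        assert evidence_join(a, b) == expected
        assert evidence_join(b, a) == expected


class TestAddInteractions:
    def test_duplicate_rows_collapse_to_one_edge(self):
        net = RegulatoryNetwork()
        row = {"regulator": "A", "target": "B", "effect": Effect.ACTIVATION,
               "evidence": Evidence.WEAK}
        out = add_interactions(net, [row, row])
        assert len(out.interactions) == 1
        assert out.interactions[("A", "B")].effect == Effect.ACTIVATION

    def test_idempotent_on_repeated_application(self):
        rows = [
            {"regulator": "A", "target": "B", "effect": Effect.ACTIVATION},
            {"regulator": "B", "target": "C", "effect": Effect.REPRESSION,
             "evidence": Evidence.STRONG},
        ]
        once = add_interactions(RegulatoryNetwork(), rows)
        twice = add_interactions(once, rows)
        assert once == twice

    def test_conflicting_effects_reconcile_to_dual(self):
        rows = [
            {"regulator": "A", "target": "B", "effect": Effect.ACTIVATION},
            {"regulator": "A", "target": "B", "effect": Effect.REPRESSION},
        ]
        out = add_interactions(RegulatoryNetwork(), rows)
        assert out.interactions[("A", "B")].effect == Effect.DUAL

    def test_sigma_factor_edges_coerced_to_activation(self):
        net = RegulatoryNetwork()
        net.add_node(GeneNode(node_id="sigA", is_sigma_factor=True))
        out = add_interactions(
            net, [{"regulator": "sigA", "target": "B", "effect": Effect.REPRESSION}]
        )
        assert out.interactions[("sigA", "B")].effect == Effect.ACTIVATION

    @pytest.mark.parametrize("bad_key", ["regulator", "target"])
    def test_malformed_row_reports_index(self, bad_key):
        rows = [
            {"regulator": "A", "target": "B"},
            {"regulator": "A", "target": "B"} | {bad_key: " "},
        ]
        with pytest.raises(RawInteractionError) as err:
            add_interactions(RegulatoryNetwork(), rows)
        assert err.value.row_index == 1


class TestCollapseComplexes:
    def test_dependent_subunits_replaced_by_complex(self):
        net = make_network([("r", "s1"), ("r", "s2"), ("s1", "t"), ("s2", "t")])
        out = collapse_complexes(net, [("C", ["s1", "s2"], ["t"])])
        assert set(out.nodes) == {"r", "C", "t"}
        assert set(out.interactions) == {("r", "C"), ("C", "t")}

    def test_independent_subunit_keeps_its_own_regulation(self):
        net = make_network(
            [("r", "s1"), ("r", "s2"), ("s1", "t"), ("s2", "t"), ("s1", "u")]
        )
        out = collapse_complexes(net, [("C", ["s1", "s2"], ["t"])])
        assert set(out.nodes) == {"r", "s1", "s2", "C", "t", "u"}
        assert set(out.interactions) == {
            ("s1", "C"), ("s2", "C"), ("s1", "u"), ("C", "t"), ("r", "s1"), ("r", "s2"),
        }
        assert out.interactions[("s1", "C")].effect == Effect.ACTIVATION

    def test_empty_definitions_leave_network_unchanged(self):
        net = make_network([("a", "b")])
        assert collapse_complexes(net, []) == net

    def test_too_few_subunits_rejected(self):
        net = make_network([("r", "s1")])
        with pytest.raises(ValueError, match="at least 2 subunits"):
            collapse_complexes(net, [("C", ["s1"], ["t"])])

    def test_unknown_subunit_named_in_error(self):
        net = make_network([("r", "s1")])
        with pytest.raises(ValueError, match="ghost"):
            collapse_complexes(net, [("C", ["s1", "ghost"], ["t"])])

    def test_regulated_targets_reachable_set_preserved(self):
        """Collapsing never changes which genes an outside regulator reaches."""
        import networkx as nx

        net = make_network(
            [("r", "s1"), ("r", "s2"), ("s1", "t1"), ("s2", "t1"), ("s1", "t2"),
             ("s2", "t2"), ("x", "r")]
        )
        out = collapse_complexes(net, [("C", ["s1", "s2"], ["t1", "t2"])])
        before = nx.descendants(net.to_networkx(), "x")
        after = nx.descendants(out.to_networkx(), "x")
        gene_targets_before = {n for n in before if n in {"t1", "t2"}}
        gene_targets_after = {n for n in after if n in {"t1", "t2"}}
        assert gene_targets_before == gene_targets_after


class TestGenomicCoverage:
    def test_plain_percentage(self):
        net = RegulatoryNetwork(genome_gene_count=500)
        for i in range(100):
            net.ensure_node(f"g{i}")
        assert genomic_coverage(net) == pytest.approx(20.0)

    def test_complex_nodes_do_not_count(self):
        net = RegulatoryNetwork(genome_gene_count=500)
        for i in range(100):
            net.ensure_node(f"g{i}")
        for i in range(3):
            net.add_node(
                GeneNode(node_id=f"C{i}", node_kind="complex",
                         subunit_ids={"g0", "g1"})
            )
        assert genomic_coverage(net) == pytest.approx(20.0)

    def test_missing_genome_size_is_an_error(self):
        net = RegulatoryNetwork()
        net.ensure_node("a")
        with pytest.raises(ValueError, match="genome_gene_count"):
            genomic_coverage(net)


class TestProjections:
    def test_strong_projection_keeps_only_strong_edges(self):
        net = make_network(
            [
                ("a", "b", Effect.ACTIVATION, Evidence.STRONG),
                ("b", "c", Effect.ACTIVATION, Evidence.STRONG),
                ("c", "d", Effect.ACTIVATION, Evidence.WEAK),
                ("d", "e", Effect.ACTIVATION, Evidence.WEAK),
                ("e", "f", Effect.ACTIVATION, Evidence.UNKNOWN),
            ]
        )
        strong = project_subnetwork(net, evidence="strong")
        assert len(strong.interactions) == 2
        assert set(strong.nodes) == {"a", "b", "c"}

    def test_all_weak_network_projects_to_empty(self):
        net = make_network([("a", "b", Effect.ACTIVATION, Evidence.WEAK)])
        strong = project_subnetwork(net, evidence="strong")
        assert not strong.interactions and not strong.nodes

    def test_strong_projection_is_monotone(self):
        net = make_network(
            [("a", "b", Effect.ACTIVATION, Evidence.STRONG),
             ("b", "c", Effect.REPRESSION, Evidence.WEAK)]
        )
        strong = project_subnetwork(net, evidence="strong")
        assert set(strong.interactions) <= set(net.interactions)

    def test_module_projection_returns_planted_module(self, planted):
        from regnet import annotate_network_with_classes

        network, classes, partition = planted
        labelled = annotate_network_with_classes(network, classes, partition)
        module_id = sorted(partition.modules)[0]
        sub = project_subnetwork(labelled, module_id=module_id)
        assert set(sub.nodes) == partition.modules[module_id]

    def test_unknown_module_is_an_error(self):
        net = make_network([("a", "b")])
        with pytest.raises(ValueError, match="unknown module"):
            project_subnetwork(net, module_id="99")


class TestJson:
    def test_empty_network_has_empty_arrays(self):
        import json

        doc = json.loads(to_json(RegulatoryNetwork(organism="X")))
        assert doc["nodes"] == [] and doc["edges"] == []

    def test_round_trip_identity(self):
        net = make_network(
            [("sigA", "b", Effect.REPRESSION, Evidence.STRONG), ("b", "c")],
            genome=100,
            sigma=["sigA"],
        )
        net.nodes["b"].synonyms.add("oldB")
        net.nodes["b"].product = "hypothetical protein"
        assert from_json(to_json(net)) == net

    def test_round_trip_preserves_complexes_and_classes(self, planted):
        from regnet import annotate_network_with_classes

        network, classes, partition = planted
        labelled = annotate_network_with_classes(network, classes, partition)
        labelled.add_node(
            GeneNode(node_id="cplx", node_kind="complex",
                     subunit_ids={"gr1", "gr2"})
        )
        assert from_json(to_json(labelled)) == labelled

    def test_edge_with_unknown_node_reports_path(self):
        text = """{
 "metadata": {"organism": "X", "genome_gene_count": null, "sources": {}},
 "nodes": [{"id": "a", "canonical": "a", "locus_tag": null, "synonyms": [],
            "kind": "gene", "sigma": false, "rna": false, "subunits": [],
            "product": null, "class": null, "module": null}],
 "edges": [{"source": "a", "target": "ghost", "effect": "activation",
            "evidence": "weak", "sources": []}]
}"""
        with pytest.raises(SchemaError) as err:
            from_json(text)
        assert err.value.path == "edges[0].target"

    @pytest.mark.parametrize(
        "mutation, path",
        [
            (None, None),  # baseline sanity, no error expected
            ('"kind": "plasmid"', "nodes[0].kind"),
            ('"effect": "boost"', "edges[0].effect"),
        ],
    )
    def test_invalid_enums_report_path(self, mutation, path):
        base = """{
 "metadata": {"organism": "X", "genome_gene_count": null, "sources": {}},
 "nodes": [{"id": "a", "canonical": "a", "locus_tag": null, "synonyms": [],
            "kind": "gene", "sigma": false, "rna": false, "subunits": [],
            "product": null, "class": null, "module": null},
           {"id": "b", "canonical": "b", "locus_tag": null, "synonyms": [],
            "kind": "gene", "sigma": false, "rna": false, "subunits": [],
            "product": null, "class": null, "module": null}],
 "edges": [{"source": "a", "target": "b", "effect": "activation",
            "evidence": "weak", "sources": []}]
}"""
        if mutation is None:
            text = base
        elif mutation == '"kind": "plasmid"':
            text = base.replace('"kind": "gene"', mutation, 1)
        else:
            text = base.replace('"effect": "activation"', mutation)
        if path is None:
            from_json(text)
        else:
            with pytest.raises(SchemaError) as err:
                from_json(text)
            assert err.value.path == path
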