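import networkx as nx
import pytest

from gothemes import (
    FixtureSpec,
    OntologyError,
    attach_annotations,
    descendant_count,
    generate,
    parse_obo,
    propagate,
    prune_unannotated,
    read_gaf,
)
from gothemes.go_graph import GeneAnnotationTable

from conftest import write_gaf, write_obo


class TestParseObo:
    def test_chain_structure(self, chain_graph):
        assert sorted(chain_graph.terms) == ["T:A", "T:B", "T:C"]
        assert chain_graph.root == "T:A"
        assert chain_graph.is_a_edges() == [("T:B", "T:A"), ("T:C", "T:B")]
        assert chain_graph.name("T:B") == "beta process"

    def test_cycle_is_rejected_naming_members(self, tmp_path):
        obo = write_obo(tmp_path / "cyc.obo", """\
            [Term]
            id: T:A
            name: a

            [Term]
            id: T:B
            name: b
            is_a: T:A ! a
            is_a: T:C ! c

            [Term]
            id: T:C
            name: c
            is_a: T:B ! b
            """)
        with pytest.raises(OntologyError, match="T:B.*T:C|cycle"):
            parse_obo(obo)

    def test_namespace_filter_keeps_only_requested_terms(self, tmp_path):
        obo = write_obo(tmp_path / "mix.obo", """\
            [Term]
            id: T:A
            name: bp root

            [Term]
            id: T:B
            name: bp child
            is_a: T:A ! bp root

            [Term]
            id: T:M
            name: mf root
            namespace: molecular_function
            """)
        g = parse_obo(obo, namespace="biological_process")
        assert sorted(g.terms) == ["T:A", "T:B"]

    def test_multiple_roots_rejected(self, tmp_path):
        obo = write_obo(tmp_path / "two.obo", """\
            [Term]
            id: T:A
            name: a

            [Term]
            id: T:B
            name: b
            """)
        with pytest.raises(OntologyError, match="root"):
            parse_obo(obo)


class TestAnnotations:
    def test_direct_genes_attached_to_leaf(self, chain_graph):
        assert chain_graph.direct_genes["T:C"] == {"g1"}

    def test_duplicate_evidence_rows_stored_once(self, tmp_path):
        obo = write_obo(tmp_path / "c.obo", """\
            [Term]
            id: T:A
            name: a
            """)
        gaf = write_gaf(tmp_path / "c.gaf",
                        [("g1", "T:A", "IEA"), ("g1", "T:A", "IDA")])
        table = read_gaf(gaf)
        assert len(table) == 1
        g = attach_annotations(parse_obo(obo), table)
        assert g.direct_genes["T:A"] == {"g1"}

    def test_unmapped_terms_counted_not_dropped(self, tmp_path):
        obo = write_obo(tmp_path / "c.obo", """\
            [Term]
            id: T:A
            name: a
            """)
        gaf = write_gaf(tmp_path / "c.gaf", [("g1", "T:A"), ("g2", "T:GONE")])
        g = attach_annotations(parse_obo(obo), read_gaf(gaf))
        assert g.unmapped_terms == {"T:GONE": 1}

    def test_empty_table_is_an_error(self, tmp_path):
        obo = write_obo(tmp_path / "c.obo", """\
            [Term]
            id: T:A
            name: a
            """)
        empty = GeneAnnotationTable(
            frame=read_gaf(write_gaf(tmp_path / "c.gaf", [("g", "T:A")])).frame.iloc[:0]
        )
        with pytest.raises(ValueError, match="empty"):
            attach_annotations(parse_obo(obo), empty)

    def test_evidence_filter(self, tmp_path):
        gaf = write_gaf(tmp_path / "c.gaf",
                        [("g1", "T:A", "IEA"), ("g2", "T:A", "IDA")])
        table = read_gaf(gaf, exclude_evidence={"IEA"})
        assert list(table.frame["gene"]) == ["g2"]

    def test_direct_counts_match_hand_tally(self, tmp_path):
        rows = [(f"g{i}", term) for i, term in enumerate(
            ["T:A"] * 3 + ["T:B"] * 4 + ["T:C"] * 2 + ["T:B"])]
        obo = write_obo(tmp_path / "t.obo", """\
            [Term]
            id: T:A
            name: a

            [Term]
            id: T:B
            name: b
            is_a: T:A ! a

            [Term]
            id: T:C
            name: c
            is_a: T:A ! a

            [Term]
            id: T:D
            name: d
            is_a: T:C ! c
            """)
        g = attach_annotations(parse_obo(obo),
                               read_gaf(write_gaf(tmp_path / "t.gaf", rows)))
        assert {t: len(s) for t, s in g.direct_genes.items()} == {
            "T:A": 3, "T:B": 5, "T:C": 2}


class TestPropagation:
    def test_chain_closure(self, chain_graph):
        for term in ("T:A", "T:B", "T:C"):
            assert chain_graph.cumulative_genes[term] == {"g1"}

    def test_diamond_counts_gene_once(self, diamond_graph):
        assert diamond_graph.cumulative_genes["T:A"] == {"g1"}

    def test_idempotent(self, chain_graph):
        once = {t: set(s) for t, s in chain_graph.cumulative_genes.items()}
        propagate(chain_graph)
        assert chain_graph.cumulative_genes == once

    def test_matches_bruteforce_subtree_union(self, tmp_path):
        spec = FixtureSpec(seed=11, depth=4, branching=2, diamond=True,
                           n_genes=40)
        bundle = generate(spec, tmp_path)
        g = attach_annotations(parse_obo(bundle.obo), read_gaf(bundle.gaf))
        propagate(g)
        for term in g.terms:
            expected = set()
            for s in nx.ancestors(g.graph, term) | {term}:
                expected |= g.direct_genes.get(s, set())
            assert g.cumulative_genes[term] == expected

    def test_subtree_containment_along_edges(self, tmp_path):
        bundle = generate(FixtureSpec(seed=3, depth=4, branching=2,
                                      diamond=True, n_genes=30), tmp_path)
        g = attach_annotations(parse_obo(bundle.obo), read_gaf(bundle.gaf))
        for child, parent in g.is_a_edges():
            assert g.subtree(child) <= g.subtree(parent)


class TestPruning:
    def test_ancestors_of_annotated_leaf_retained(self, chain_graph):
        pruned = prune_unannotated(chain_graph)
        assert sorted(pruned.terms) == ["T:A", "T:B", "T:C"]

    def test_barren_branch_removed_and_reconnected(self, tmp_path):
        obo = write_obo(tmp_path / "p.obo", """\
            [Term]
            id: T:A
            name: a

            [Term]
            id: T:B
            name: b
            is_a: T:A ! a

            [Term]
            id: T:C
            name: c
            is_a: T:B ! b

            [Term]
            id: T:X
            name: barren
            is_a: T:A ! a
            """)
        gaf = write_gaf(tmp_path / "p.gaf", [("g1", "T:C")])
        g = propagate(attach_annotations(parse_obo(obo), read_gaf(gaf)))
        pruned = prune_unannotated(g)
        assert "T:X" not in pruned
        assert nx.has_path(pruned.graph, "T:C", pruned.root)

    def test_removed_parent_bridged_to_nearest_ancestor(self, tmp_path):
        # B is unannotated; C must re-attach directly to A
        obo = write_obo(tmp_path / "b.obo", """\
            [Term]
            id: T:A
            name: a

            [Term]
            id: T:B
            name: b
            is_a: T:A ! a

            [Term]
            id: T:C
            name: c
            is_a: T:B ! b

            [Term]
            id: T:D
            name: d
            is_a: T:B ! b
            """)
        gaf = write_gaf(tmp_path / "b.gaf", [("g1", "T:C"), ("g1", "T:A")])
        g = propagate(attach_annotations(parse_obo(obo), read_gaf(gaf)))
        # make B cumulative nonempty via C; D stays empty
        pruned = prune_unannotated(g)
        assert "T:D" not in pruned
        assert ("T:C", "T:B") in pruned.graph.edges

    def test_retained_set_matches_bruteforce_filter(self, tmp_path):
        bundle = generate(FixtureSpec(seed=9, depth=5, branching=2,
                                      n_genes=8, module_size=4,
                                      annotations_per_gene=1),
                          tmp_path)
        g = attach_annotations(parse_obo(bundle.obo), read_gaf(bundle.gaf))
        propagate(g)
        expected = {t for t in g.terms if g.cumulative_genes[t]}
        pruned = prune_unannotated(g)
        assert set(pruned.terms) == expected
        # pruning never removes an ancestor of a retained term
        for term in pruned.terms:
            assert nx.descendants(g.graph, term) <= set(g.terms)

    def test_unannotated_root_is_an_error(self, tmp_path):
        obo = write_obo(tmp_path / "e.obo", """\
            [Term]
            id: T:A
            name: a
            """)
        gaf = write_gaf(tmp_path / "e.gaf", [("g1", "T:A")])
        g = parse_obo(obo)
        attach_annotations(g, read_gaf(gaf))
        g.direct_genes = {}
        propagate(g)
        with pytest.raises(ValueError):
            prune_unannotated(g)


class TestDescendantCount:
    def test_conventions(self, chain_graph, diamond_graph):
        assert descendant_count(chain_graph, "T:C") == 1  # leaf counts itself
        assert descendant_count(chain_graph, "T:A") == 3
        # shared descendant counted once
        assert descendant_count(diamond_graph, "T:A") == 4

    def test_unknown_term(self, chain_graph):
        with pytest.raises(KeyError):
            descendant_count(chain_graph, "T:NOPE")
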