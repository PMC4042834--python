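import json
from itertools import combinations

import numpy as np
import pytest

from gothemes import (
    FixtureSpec,
    attach_annotations,
    attach_documents,
    build_all_profiles,
    generate,
    load_document_store,
    parse_obo,
    propagate,
    prune_unannotated,
    read_gaf,
    read_gmt,
    read_ppi,
    weight_all_edges,
)
from gothemes.fixtures import make_ontology


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(depth=1),
            dict(branching=1),
            dict(vocab_size=5),
            dict(noise_rate=1.5),
            dict(n_genes=10),  # smaller than planted module budget
            dict(module_depth=4),  # at leaf level for depth 5
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            FixtureSpec(seed=1, **kw)

    def test_uninformative_ppi_design_warns(self):
        with pytest.warns(UserWarning, match="uninformative"):
            FixtureSpec(seed=1, p_in=0.1, p_out=0.5)


class TestOntologyGeneration:
    def test_term_count_geometric(self, tmp_path):
        onto = make_ontology(FixtureSpec(seed=1, depth=3, branching=2,
                                         n_genes=20, module_size=2,
                                         module_depth=1),
                             tmp_path / "o.obo")
        assert len(onto.terms) == 7  # 1 + 2 + 4

    def test_diamond_option_creates_multiparent_term(self, tmp_path):
        spec = FixtureSpec(seed=1, depth=4, branching=2, diamond=True,
                           n_genes=20, module_size=2)
        onto = make_ontology(spec, tmp_path / "d.obo")
        parents = {}
        for child, parent in onto.edges:
            parents.setdefault(child, []).append(parent)
        assert any(len(ps) == 2 for ps in parents.values())

    def test_round_trip_through_parser(self, tmp_path):
        spec = FixtureSpec(seed=2, depth=4, branching=3)
        onto = make_ontology(spec, tmp_path / "r.obo")
        g = parse_obo(tmp_path / "r.obo")
        assert set(g.terms) == set(onto.terms)
        assert g.root == onto.root


class TestDeterminism:
    def test_bundles_bitwise_identical_for_same_seed(self, tmp_path):
        spec = FixtureSpec(seed=33, depth=4, branching=2, n_genes=40,
                           module_size=5)
        a = generate(spec, tmp_path / "a")
        b = generate(spec, tmp_path / "b")
        for name in ("obo", "gaf", "docs", "term_docs", "gmt", "ppi"):
            assert getattr(a, name).read_bytes() == getattr(b, name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        base = dict(depth=4, branching=2, n_genes=40, module_size=5)
        a = generate(FixtureSpec(seed=1, **base), tmp_path / "a")
        b = generate(FixtureSpec(seed=2, **base), tmp_path / "b")
        assert a.gaf.read_bytes() != b.gaf.read_bytes()


class TestAnnotationsGeneration:
    def test_zero_noise_keeps_modules_inside_their_subtrees(self, tmp_path):
        spec = FixtureSpec(seed=5, noise_rate=0.0, module_scatter_rate=0.0)
        bundle = generate(spec, tmp_path)
        onto = bundle.ontology
        by_gene = {}
        for gene, term in bundle.annotations.rows:
            by_gene.setdefault(gene, set()).add(term)
        for name, genes in bundle.annotations.modules.items():
            root = bundle.annotations.module_roots[name]
            allowed = set(onto.subtree_leaves(root))
            for gene in genes:
                assert by_gene[gene] <= allowed

    def test_full_noise_scatters_beyond_subtrees(self, tmp_path):
        spec = FixtureSpec(seed=5, noise_rate=1.0)
        bundle = generate(spec, tmp_path)
        onto = bundle.ontology
        outside = 0
        for name, genes in bundle.annotations.modules.items():
            allowed = set(onto.subtree_leaves(
                bundle.annotations.module_roots[name]))
            for gene, term in bundle.annotations.rows:
                if gene in genes and term not in allowed:
                    outside += 1
        assert outside > 0

    def test_off_module_genes_have_no_planted_annotations(self, tmp_path):
        bundle = generate(FixtureSpec(seed=6), tmp_path)
        planted = set()
        for root in bundle.annotations.module_roots.values():
            planted |= set(bundle.ontology.subtree_leaves(root))
        by_gene = {}
        for gene, term in bundle.annotations.rows:
            by_gene.setdefault(gene, set()).add(term)
        for gene in bundle.annotations.off_module_genes:
            assert by_gene[gene].isdisjoint(planted)

    def test_gaf_parses_with_package_reader(self, tmp_path):
        bundle = generate(FixtureSpec(seed=7), tmp_path)
        table = read_gaf(bundle.gaf)
        assert len(table) > 0
        assert set(table.frame["evidence"]) == {"IEA"}


class TestCorpusGeneration:
    def build_ib_weights(self, tmp_path, concentration, seed=9):
        spec = FixtureSpec(seed=seed, depth=4, branching=2, n_genes=40,
                           module_size=5, concentration=concentration)
        bundle = generate(spec, tmp_path)
        g = parse_obo(bundle.obo)
        attach_annotations(g, read_gaf(bundle.gaf))
        store = load_document_store(bundle.docs, bundle.term_docs)
        attach_documents(g, store)
        propagate(g)
        g = prune_unannotated(g)
        profiles = build_all_profiles(g, store)
        wg = weight_all_edges(g, "ib", profiles=profiles)
        return float(np.mean(list(wg.weights.values())))

    def test_high_concentration_shrinks_semantic_loss(self, tmp_path):
        # finite documents keep a sampling-noise floor, so the weights shrink
        # with concentration without reaching the zero limit exactly
        loose = self.build_ib_weights(tmp_path / "a", concentration=5.0)
        tight = self.build_ib_weights(tmp_path / "b", concentration=5e4)
        assert tight < loose / 2

    def test_sibling_topics_distinguishable(self, tmp_path):
        bundle = generate(FixtureSpec(seed=9, depth=3, branching=2,
                                      n_genes=20, module_size=2,
                                      module_depth=1, docs_per_term=5),
                          tmp_path)
        store = load_document_store(bundle.docs, bundle.term_docs)
        g = parse_obo(bundle.obo)
        attach_documents(g, store)
        propagate(g)
        profiles = build_all_profiles(g, store)
        sibs = [t for t in g.terms if g.parents(t) == [g.root]]
        p, q = (profiles[s].distribution() for s in sibs[:2])
        words = set(p) | set(q)
        tv = 0.5 * sum(abs(p.get(w, 0) - q.get(w, 0)) for w in words)
        assert tv > 0.05

    def test_docs_round_trip(self, tmp_path):
        bundle = generate(FixtureSpec(seed=10), tmp_path)
        store = load_document_store(bundle.docs, bundle.term_docs)
        assert len(store.docs) == len(bundle.ontology.terms) * 3
        first = json.loads(bundle.docs.read_text().splitlines()[0])
        assert set(first) == {"id", "title", "abstract"}


class TestBenchmarkGeneration:
    def test_extreme_probabilities_give_clean_modules(self, tmp_path):
        spec = FixtureSpec(seed=11, p_in=1.0, p_out=0.0, noise_rate=0.0)
        bundle = generate(spec, tmp_path)
        ppi = read_ppi(bundle.ppi)
        modules = list(bundle.annotations.modules.values())
        for genes in modules:
            for a, b in combinations(sorted(genes), 2):
                assert frozenset((a, b)) in ppi
        cross = [frozenset((a, b)) for a in modules[0] for b in modules[1]]
        assert all(e not in ppi for e in cross)

    def test_within_module_edge_count_matches_binomial(self, tmp_path):
        counts = []
        for seed in range(10):
            spec = FixtureSpec(seed=seed, p_in=0.5, p_out=0.0,
                               noise_rate=0.0)
            bundle = generate(spec, tmp_path / str(seed))
            ppi = read_ppi(bundle.ppi)
            genes = list(bundle.annotations.modules.values())[0]
            counts.append(sum(
                1 for a, b in combinations(sorted(genes), 2)
                if frozenset((a, b)) in ppi
            ))
        # E[I] = 0.5 * C(10,2) = 22.5, sd = sqrt(45*0.25) per draw
        expected, sd = 22.5, np.sqrt(45 * 0.25)
        assert abs(np.mean(counts) - expected) < 3 * sd / np.sqrt(len(counts))

    def test_gmt_lists_planted_modules(self, tmp_path):
        bundle = generate(FixtureSpec(seed=12), tmp_path)
        sets = {name: genes for name, _, genes in read_gmt(bundle.gmt)}
        assert sets == bundle.annotations.modules
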