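"""Ontology DAG representation: parsing, annotation, propagation, pruning.

The ontology is held as a directed acyclic graph with IS_A edges pointing
child -> parent, so the unique namespace root is the single node without
outgoing edges. Gene and document associations live in per-term dictionaries;
`propagate` closes them upward under the true-path rule (a gene annotated to
a term is implicitly annotated to every ancestor).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)


class OntologyError(ValueError):
    """Structural problem in the ontology (cycle, missing/multiple roots)."""


@dataclass
class GeneAnnotationTable:
    """Rows of (gene id, term id, evidence code), de-duplicated on (gene, term)."""

    frame: pd.DataFrame  # columns: gene, term, evidence

    def __post_init__(self) -> None:
        before = len(self.frame)
        self.frame = self.frame.drop_duplicates(subset=["gene", "term"]).reset_index(
            drop=True
        )
        self.n_duplicates_dropped = before - len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class OntologyGraph:
    """Term DAG with IS_A edges (child -> parent) and attached associations."""

    graph: nx.DiGraph
    root: str
    namespace: str
    direct_genes: dict[str, set[str]] = field(default_factory=dict)
    cumulative_genes: dict[str, set[str]] = field(default_factory=dict)
    direct_docs: dict[str, set[str]] = field(default_factory=dict)
    cumulative_docs: dict[str, set[str]] = field(default_factory=dict)
    unmapped_terms: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._subtree_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def parents(self, term: str) -> list[str]:
        return sorted(self.graph.successors(term))

    def children(self, term: str) -> list[str]:
        return sorted(self.graph.predecessors(term))

    def is_a_edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def subtree(self, term: str) -> frozenset[str]:
        """All terms in the subgraph rooted at `term`, including itself."""
        if term not in self.graph:
            raise KeyError(f"unknown term: {term}")
        cached = self._subtree_cache.get(term)
        if cached is None:
            # edges run child -> parent, so descendants are the nodes that
            # can reach `term`
            cached = frozenset(nx.ancestors(self.graph, term)) | {term}
            self._subtree_cache[term] = cached
        return cached

    def descendant_count(self, term: str) -> int:
        """|t|: number of terms in the subgraph rooted at t, self included."""
        return len(self.subtree(term))

    def annotated_genes(self) -> list[str]:
        """Genes with at least one direct annotation in this graph, sorted."""
        out: set[str] = set()
        for genes in self.direct_genes.values():
            out |= genes
        return sorted(out)

    def gene_index(self) -> dict[str, set[str]]:
        """gene id -> set of terms carrying a DIRECT annotation of that gene."""
        idx: dict[str, set[str]] = {}
        for term in self.graph.nodes:
            for g in self.direct_genes.get(term, ()):
                idx.setdefault(g, set()).add(term)
        return idx


def _check_structure(g: nx.DiGraph) -> str:
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        members = sorted({u for u, _ in cycle})
        raise OntologyError(f"IS_A cycle detected among terms: {members}")
    roots = sorted(n for n in g.nodes if g.out_degree(n) == 0)
    if len(roots) != 1:
        raise OntologyError(
            f"expected exactly one namespace root, found {len(roots)}: {roots}"
        )
    return roots[0]


def parse_obo(path, namespace: str = "biological_process") -> OntologyGraph:
    """Parse an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Only non-obsolete terms of the requested namespace and their IS_A edges
    are kept; other relationship types (part_of, regulates, ...) are counted
    and logged, never silently used. Raises :class:`OntologyError` on a cycle
    or if the namespace does not have exactly one root.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    default_ns = multi.graph.get("default-namespace", [None])
    default_ns = default_ns[0] if isinstance(default_ns, list) else default_ns

    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        ns = data.get("namespace", default_ns)
        if ns == namespace:
            g.add_node(node, name=data.get("name", node))

    skipped_relations = 0
    for child, parent, key in multi.edges(keys=True):
        if key != "is_a":
            skipped_relations += 1
            continue
        if child in g and parent in g:
            g.add_edge(child, parent)
    if skipped_relations:
        logger.info("ignored %d non-IS_A relationship edges", skipped_relations)
    if g.number_of_nodes() == 0:
        raise OntologyError(f"no terms in namespace {namespace!r}")

    root = _check_structure(g)
    return OntologyGraph(graph=g, root=root, namespace=namespace)


def read_gaf(path, exclude_evidence: set[str] | None = None) -> GeneAnnotationTable:
    """Read a GAF 2.x tab-delimited annotation file.

    Column 2 is the gene/product id, column 5 the term id, column 7 the
    evidence code (1-based). Lines starting with '!' are comments. Evidence
    codes in `exclude_evidence` (e.g. {"IEA"}) are dropped before
    de-duplication.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise ValueError(f"GAF line with {len(cols)} columns: {line[:80]!r}")
            rows.append((cols[1], cols[4], cols[6]))
    frame = pd.DataFrame(rows, columns=["gene", "term", "evidence"])
    if exclude_evidence:
        frame = frame[~frame["evidence"].isin(exclude_evidence)]
    return GeneAnnotationTable(frame=frame)


def attach_annotations(
    graph: OntologyGraph, table: GeneAnnotationTable
) -> OntologyGraph:
    """Populate `direct_genes` from an annotation table (in place).

    Annotations to terms absent from the graph are tallied in
    `graph.unmapped_terms` and logged, not silently dropped.
    """
    if len(table) == 0:
        raise ValueError("annotation table is empty; nothing downstream is computable")
    unmapped: dict[str, int] = {}
    direct: dict[str, set[str]] = {}
    for gene, term in zip(table.frame["gene"], table.frame["term"]):
        if term in graph.graph:
            direct.setdefault(term, set()).add(gene)
        else:
            unmapped[term] = unmapped.get(term, 0) + 1
    if unmapped:
        logger.warning(
            "%d annotations to %d terms outside the graph",
            sum(unmapped.values()),
            len(unmapped),
        )
    graph.direct_genes = direct
    graph.unmapped_terms = unmapped
    return graph


def _propagate_sets(graph: OntologyGraph, direct: dict[str, set[str]]):
    cumulative: dict[str, set[str]] = {}
    # topological order of child->parent edges visits children first
    for term in nx.topological_sort(graph.graph):
        acc = set(direct.get(term, ()))
        for child in graph.graph.predecessors(term):
            acc |= cumulative[child]
        cumulative[term] = acc
    return cumulative


def propagate(graph: OntologyGraph) -> OntologyGraph:
    """Close direct gene and document sets upward (true-path rule), in place."""
    graph.cumulative_genes = _propagate_sets(graph, graph.direct_genes)
    graph.cumulative_docs = _propagate_sets(graph, graph.direct_docs)
    return graph


def _nearest_kept_ancestors(
    graph: nx.DiGraph, term: str, kept: set[str], weights=None
) -> dict[str, float]:
    """Map each nearest retained ancestor to the min summed edge weight to it."""
    out: dict[str, float] = {}

    def walk(node: str, acc: float) -> None:
        for parent in graph.successors(node):
            w = acc + (weights.get((node, parent), 0.0) if weights else 0.0)
            if parent in kept:
                if parent not in out or w < out[parent]:
                    out[parent] = w
            else:
                walk(parent, w)

    walk(term, 0.0)
    return out


def prune_unannotated(graph: OntologyGraph) -> OntologyGraph:
    """Drop terms whose cumulative gene set is empty; reconnect around them.

    A retained term whose parent was removed is re-attached to the removed
    parent's nearest retained ancestors, so every retained term still reaches
    the root. Returns a new :class:`OntologyGraph`.
    """
    if not graph.cumulative_genes:
        raise ValueError("run propagate() before prune_unannotated()")
    kept = {t for t in graph.graph.nodes if graph.cumulative_genes.get(t)}
    if graph.root not in kept:
        raise OntologyError("root has no annotated descendants; nothing to keep")

    g = nx.DiGraph()
    for term in sorted(kept):
        g.add_node(term, name=graph.name(term))
    for term in sorted(kept):
        if term == graph.root:
            continue
        for anc in _nearest_kept_ancestors(graph.graph, term, kept):
            g.add_edge(term, anc)

    root = _check_structure(g)
    pruned = OntologyGraph(
        graph=g,
        root=root,
        namespace=graph.namespace,
        direct_genes={t: set(graph.direct_genes.get(t, set())) for t in kept},
        direct_docs={t: set(graph.direct_docs.get(t, set())) for t in kept},
        unmapped_terms=dict(graph.unmapped_terms),
    )
    return propagate(pruned)


def descendant_count(graph: OntologyGraph, term: str) -> int:
    """|t|, the size of the subgraph rooted at `term` (self-inclusive)."""
    return graph.descendant_count(term)
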