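"""Iterative leaf-merging summarization of a gene list.

Starting from the ontology restricted to terms that (cumulatively) annotate
at least one query gene, leaf terms are merged into their parents in order of
increasing information loss. After a merge the parent summarizes the genes of
the collapsed subtree. A merge is accepted only while the resulting gene set
stays functionally coherent under the null model; when a merge would produce
an incoherent set, the child is frozen as a final summarizing term. The
output is a set of possibly overlapping modules, each labelled by its
summarizing term with the coherence statistic and p-value of its gene set.

Two details matter:

* the gene set tested by the gate is the parent's post-merge *summarizing*
  set — the query genes covered by its whole remaining subtree (a
  summarizing term annotates the genes of the subgraph beneath it), not just
  the genes already accumulated by earlier merges. Genes whose only route to
  the parent runs through an already-frozen lineage are excluded: freezing
  stops one lineage without stopping its siblings.
* a lineage often climbs through ancestors that contribute no new query
  genes before its first rejected merge, so the frozen head can sit above
  the informative term. Each emitted module is therefore relabelled to the
  most specific term of its collapsed lineage whose subtree still covers
  every member gene (at least one direct annotation per gene) — deeper means
  more informative at no extra information loss.

Merge-order losses come from the full weighted graph (a collapsed chain of
pruned-away terms contributes the summed weight along the cheapest path);
the gate statistic and the null model both live on the full pruned graph, so
gate p-values are calibrated against exactly the statistic that was sampled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .coherence import AugmentedGraph, gene_set_statistic
from .go_graph import OntologyGraph, _nearest_kept_ancestors
from .info_loss import WeightedGraph
from .null_model import NullModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryModule:
    """One output unit: a summarizing term and the query genes it covers."""

    term: str
    name: str
    genes: frozenset[str]
    n: int
    statistic: float | None
    p_value: float | None
    metric: str
    scheme: str
    subsumed: tuple[str, ...]
    below_min_size: bool = False


@dataclass(frozen=True)
class Merge:
    child: str
    parent: str
    loss: float


@dataclass
class MergeState:
    """Active working graph during summarization.

    `active` holds the remaining terms with IS_A edges child -> parent
    annotated with a 'loss' attribute; `genes[t]` is the set of query genes
    term t currently summarizes; `subsumed[t]` the original terms collapsed
    into it.
    """

    active: nx.DiGraph
    genes: dict[str, set[str]]
    subsumed: dict[str, list[str]] = field(default_factory=dict)

    def leaves(self) -> list[str]:
        return sorted(t for t in self.active if self.active.in_degree(t) == 0)

    def candidate_merges(self) -> list[Merge]:
        """Current leaves paired with their minimum-loss parent, sorted
        ascending by (loss, child id); a multi-parent leaf goes to the parent
        minimizing the loss, ties broken by term id."""
        out = []
        for leaf in self.leaves():
            parents = [
                (self.active[leaf][p]["loss"], p) for p in self.active.successors(leaf)
            ]
            if not parents:
                continue
            loss, parent = min(parents)
            out.append(Merge(child=leaf, parent=parent, loss=loss))
        out.sort(key=lambda m: (m.loss, m.child))
        return out

    def potential(self, term: str) -> set[str]:
        """Query genes the term would summarize: union over its active
        subtree (itself plus all active descendants). Frozen lineages have
        left the graph, so their genes are excluded unless reachable via
        another live path."""
        out: set[str] = set()
        stack = [term]
        seen = set()
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            out |= self.genes[t]
            stack.extend(self.active.predecessors(t))
        return out

    def apply_merge(self, merge: Merge) -> None:
        """Collapse child into parent: union gene sets, record provenance."""
        self.genes[merge.parent] |= self.genes[merge.child]
        self.subsumed.setdefault(merge.parent, []).extend(
            [merge.child] + self.subsumed.get(merge.child, [])
        )
        self._drop(merge.child)

    def freeze(self, term: str) -> None:
        """Remove a term whose lineage has stopped; genes stay with it."""
        self._drop(term)

    def _drop(self, term: str) -> None:
        self.active.remove_node(term)
        # keep genes/subsumed entries: freeze() callers still read them


def _restrict_to_query(wg: WeightedGraph, query: set[str]) -> MergeState:
    """Build the active graph over terms whose subtree annotates >=1 query
    gene; edges through pruned-away terms carry the summed path loss."""
    ontology = wg.ontology
    direct = {
        t: set(g for g in ontology.direct_genes.get(t, ()) if g in query)
        for t in ontology.graph.nodes
    }
    # cumulative query-gene coverage via the subtree closure
    kept = set()
    for term in ontology.graph.nodes:
        if any(direct[s] for s in ontology.subtree(term)):
            kept.add(term)
    if not kept:
        raise ValueError("no query gene maps into the graph")

    g = nx.DiGraph()
    for term in sorted(kept):
        g.add_node(term)
    for term in sorted(kept):
        for anc, loss in sorted(
            _nearest_kept_ancestors(ontology.graph, term, kept, wg.weights).items()
        ):
            g.add_edge(term, anc, loss=loss)
    return MergeState(active=g, genes={t: set(direct[t]) for t in sorted(kept)})


def coherence_gate(
    genes,
    wgraph,
    null: NullModel,
    p_cutoff: float,
    gene_index=None,
) -> tuple[bool, float | None, float | None, bool]:
    """Test whether a (post-merge) gene set passes the coherence cutoff.

    Returns (accept, statistic, p_value, below_min_size). Sets smaller than
    the smallest trained null size are not testable and auto-pass, flagged.
    """
    genes = set(genes)
    if len(genes) < null.min_size:
        return True, None, None, True
    stat = gene_set_statistic(genes, wgraph, gene_index=gene_index)
    p = null.p_value(len(genes), stat.value)
    return p <= p_cutoff, stat.value, p, False


def summarize(
    gene_list,
    wgraph,
    null: NullModel,
    p_cutoff: float = 0.01,
) -> list[SummaryModule]:
    """Partition a gene list into coherent modules labelled by ontology terms.

    Returns modules sorted by term id; every query gene with at least one
    mapped annotation appears in at least one module, and modules may
    overlap (a gene annotated in two lineages belongs to both).
    """
    base = wgraph.base if isinstance(wgraph, AugmentedGraph) else wgraph
    scheme = "augmented" if isinstance(wgraph, AugmentedGraph) else "plain"
    if (null.samples.metric, null.samples.scheme) != (base.metric, scheme):
        raise ValueError(
            "null model was fitted for "
            f"({null.samples.metric}, {null.samples.scheme}), graph is "
            f"({base.metric}, {scheme})"
        )
    ontology: OntologyGraph = base.ontology
    gene_index = ontology.gene_index()
    query = set(gene_list)
    mapped = {g for g in query if g in gene_index}
    unmapped = sorted(query - mapped)
    if not mapped:
        raise ValueError("no query gene maps into the graph")
    if unmapped:
        logger.warning("%d query genes not annotated in the graph: %s",
                       len(unmapped), unmapped)

    state = _restrict_to_query(base, mapped)
    modules: list[SummaryModule] = []

    def relabel(term: str) -> str:
        """Most specific term of the collapsed lineage that still covers
        every member gene (>=1 direct annotation inside its subtree)."""
        genes = state.genes[term]
        if not genes:
            return term
        candidates = sorted(
            {term, *state.subsumed.get(term, ())},
            key=lambda t: (ontology.descendant_count(t), t),
        )
        for t in candidates:
            sub = ontology.subtree(t)
            if all(not gene_index[g].isdisjoint(sub) for g in genes):
                return t
        return term

    def emit(term: str) -> None:
        genes = frozenset(state.genes[term])
        label = relabel(term)
        stat_value = p = None
        small = len(genes) < null.min_size
        if not small:
            stat = gene_set_statistic(genes, wgraph, gene_index=gene_index)
            stat_value = stat.value
            p = null.p_value(len(genes), stat_value)
        lineage = {term, *state.subsumed.get(term, ())}
        modules.append(
            SummaryModule(
                term=label,
                name=ontology.name(label),
                genes=genes,
                n=len(genes),
                statistic=stat_value,
                p_value=p,
                metric=base.metric,
                scheme=scheme,
                subsumed=tuple(sorted(lineage - {label})),
                below_min_size=small,
            )
        )

    while True:
        candidates = state.candidate_merges()
        if not candidates:
            break
        merge = candidates[0]
        # the set the merge would lead to: everything the parent's remaining
        # subtree summarizes (the child's genes are part of it)
        merged_genes = state.potential(merge.parent)
        accept, _, _, _ = coherence_gate(
            merged_genes, wgraph, null, p_cutoff, gene_index
        )
        if accept:
            state.apply_merge(merge)
        else:
            emit(merge.child)
            state.freeze(merge.child)

    # remaining active terms (parentless lineage heads) become modules
    for term in sorted(state.active.nodes):
        if state.genes[term]:
            emit(term)

    modules.sort(key=lambda m: m.term)
    covered = set().union(*(m.genes for m in modules)) if modules else set()
    assert mapped <= covered, "every mapped query gene must be covered"
    return modules


def modules_to_frame(modules) -> pd.DataFrame:
    rows = [
        {
            "term": m.term,
            "name": m.name,
            "n": m.n,
            "y_s": m.statistic,
            "p": m.p_value,
            "genes": ";".join(sorted(m.genes)),
        }
        for m in modules
    ]
    return pd.DataFrame(rows, columns=["term", "name", "n", "y_s", "p", "genes"])


def write_modules(modules, tsv_path, json_path=None) -> None:
    """TSV report plus optional JSON with subsumed-term provenance."""
    modules_to_frame(modules).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {
                "term": m.term,
                "name": m.name,
                "genes": sorted(m.genes),
                "n": m.n,
                "statistic": m.statistic,
                "p_value": m.p_value,
                "metric": m.metric,
                "scheme": m.scheme,
                "subsumed": list(m.subsumed),
                "below_min_size": m.below_min_size,
            }
            for m in modules
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one id per line, '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out
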