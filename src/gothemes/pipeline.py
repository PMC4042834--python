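"""Convenience wiring of the full pipeline from files on disk to a scored
graph, for scripts and interactive use."""

from __future__ import annotations

from .coherence import augment
from .corpus import attach_documents, build_all_profiles, load_document_store
from .go_graph import (
    OntologyGraph,
    attach_annotations,
    parse_obo,
    propagate,
    prune_unannotated,
    read_gaf,
)
from .info_loss import weight_all_edges


def load_annotated_graph(
    obo_path,
    gaf_path,
    docs_path=None,
    term_docs_path=None,
    namespace: str = "biological_process",
    exclude_evidence=None,
) -> tuple[OntologyGraph, object | None]:
    """Parse, annotate, (optionally) attach documents, propagate and prune.

    Returns the pruned graph and the document store (None when no corpus is
    given).
    """
    graph = parse_obo(obo_path, namespace=namespace)
    attach_annotations(graph, read_gaf(gaf_path, exclude_evidence=exclude_evidence))
    store = None
    if docs_path is not None and term_docs_path is not None:
        store = load_document_store(docs_path, term_docs_path)
        attach_documents(graph, store)
    propagate(graph)
    return prune_unannotated(graph), store


def scored_graph(graph: OntologyGraph, metric: str = "ic",
                 scheme: str = "augmented", store=None):
    """Weight the edges under `metric` and, for the augmented scheme, add
    gene-sharing shortcut edges. Returns the graph the statistic runs on."""
    profiles = None
    if metric == "ib":
        if store is None:
            raise ValueError("the IB metric needs a document store")
        profiles = build_all_profiles(graph, store)
    wg = weight_all_edges(graph, metric=metric, profiles=profiles)
    return augment(wg) if scheme == "augmented" else wg
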