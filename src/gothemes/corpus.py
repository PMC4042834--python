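"""Per-term word-usage profiles from term names and associated documents.

Each ontology term gets a word-frequency profile p(w|t) built from the names
and descriptions of every term in its subtree plus the titles and abstracts
of all documents propagated to it. Aggregating the whole subtree (not just
documents) guarantees that a child's profile support is contained in its
parent's, which keeps the Kullback-Leibler divergence between them finite.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field

from ._porter import stem
from .go_graph import OntologyGraph

_TOKEN_RE = re.compile(r"[a-z0-9]+")

# standard English stopword list (function words only; frozen)
STOPWORDS = frozenset(
    """a about above after again against all am an and any are as at be because
    been before being below between both but by can cannot could did do does
    doing down during each few for from further had has have having he her here
    hers herself him himself his how i if in into is it its itself just me more
    most my myself no nor not now of off on once only or other our ours
    ourselves out over own same she should so some such than that the their
    theirs them themselves then there these they this those through to too
    under until up very was we were what when where which while who whom why
    will with you your yours yourself yourselves""".split()
)


def preprocess(text: str) -> list[str]:
    """Tokenize, lowercase, drop stopwords and punctuation, Porter-stem."""
    tokens = _TOKEN_RE.findall(text.lower())
    return [stem(t) for t in tokens if t not in STOPWORDS]


@dataclass
class WordProfile:
    """Word-frequency vector for one term; p(w|t) = counts[w] / total."""

    counts: Counter = field(default_factory=Counter)
    total: int = 0

    @classmethod
    def from_tokens(cls, tokens) -> "WordProfile":
        c = Counter(tokens)
        return cls(counts=c, total=sum(c.values()))

    @property
    def usable(self) -> bool:
        return self.total > 0

    def distribution(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {w: n / self.total for w, n in self.counts.items()}

    def __add__(self, other: "WordProfile") -> "WordProfile":
        return WordProfile(counts=self.counts + other.counts,
                           total=self.total + other.total)


@dataclass
class DocumentStore:
    """Plain-text document records (title + abstract) keyed by document id,
    plus a term -> document-ids association map."""

    docs: dict[str, tuple[str, str]] = field(default_factory=dict)
    term_docs: dict[str, set[str]] = field(default_factory=dict)

    def tokens(self, doc_id: str) -> list[str]:
        title, abstract = self.docs[doc_id]
        return preprocess(title) + preprocess(abstract)


def read_jsonl_docs(path) -> dict[str, tuple[str, str]]:
    """Read a JSONL document store: one {id, title, abstract} object per line."""
    docs: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            docs[str(rec["id"])] = (rec.get("title", ""), rec.get("abstract", ""))
    return docs


def read_term_doc_map(path) -> dict[str, set[str]]:
    """Read a two-column TSV mapping term id -> document id."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, doc = line.split("\t")[:2]
            mapping.setdefault(term, set()).add(doc)
    return mapping


def load_document_store(docs_path, map_path) -> DocumentStore:
    return DocumentStore(docs=read_jsonl_docs(docs_path),
                         term_docs=read_term_doc_map(map_path))


def attach_documents(graph: OntologyGraph, store: DocumentStore) -> OntologyGraph:
    """Populate `direct_docs` on the graph from the store's term->doc map."""
    graph.direct_docs = {
        t: set(ids) for t, ids in store.term_docs.items() if t in graph.graph
    }
    return graph


def _term_own_tokens(graph: OntologyGraph, term: str) -> list[str]:
    data = graph.graph.nodes[term]
    toks = preprocess(data.get("name", ""))
    definition = data.get("def", "")
    if definition:
        toks += preprocess(definition)
    return toks


def build_profile(term: str, graph: OntologyGraph, store: DocumentStore) -> WordProfile:
    """Cumulative word profile of one term.

    Aggregates the name/description tokens of every term in the subtree
    rooted at `term` and the title+abstract tokens of every document
    propagated to it (each document counted once, even under diamonds).
    """
    if not graph.cumulative_docs and graph.direct_docs:
        raise ValueError("run propagate() after attach_documents()")
    counts: Counter = Counter()
    for t in sorted(graph.subtree(term)):
        counts.update(_term_own_tokens(graph, t))
    for doc_id in sorted(graph.cumulative_docs.get(term, ())):
        counts.update(store.tokens(doc_id))
    return WordProfile(counts=counts, total=sum(counts.values()))


def build_all_profiles(
    graph: OntologyGraph, store: DocumentStore
) -> dict[str, WordProfile]:
    """Profiles for every term; document/name tokenization done once each."""
    doc_tokens = {d: Counter(store.tokens(d)) for d in store.docs}
    own_tokens = {t: Counter(_term_own_tokens(graph, t)) for t in graph.graph.nodes}
    profiles: dict[str, WordProfile] = {}
    for term in graph.graph.nodes:
        counts: Counter = Counter()
        for t in graph.subtree(term):
            counts.update(own_tokens[t])
        for doc_id in graph.cumulative_docs.get(term, ()):
            counts.update(doc_tokens[doc_id])
        profiles[term] = WordProfile(counts=counts, total=sum(counts.values()))
    return profiles
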