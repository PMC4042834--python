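"""Parent-child edge weights: information lost when a child term is collapsed
into its parent.

Two metrics are provided, both in nats (natural log throughout):

* **IB** (information-bottleneck, semantic context): the child's word-usage
  profile is replaced by the parent's. The loss is

      delta_I(t_i) = p(t_i) * pi_i * D_KL( p(w|t_i) || p(w|t_p) )

  with p(t_i) = |t_i| / |t_root| and pi_i = |t_i| / |t_p|, where |t| is the
  self-inclusive descendant count of term t. The pi-weighted single KL term
  is the shipped default; a symmetric Jensen-Shannon variant against the
  pi-mixture is available behind a flag for comparison.

* **IC** (information content, gene information): IC(t) = -ln P(t), where
  P(t) is the term's share of all (gene, term) annotation instances
  accumulated over its subtree. The edge weight is the absolute IC
  difference, which under upward propagation equals IC(child) - IC(parent)
  and is nonnegative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .corpus import WordProfile
from .go_graph import OntologyGraph


class SupportError(ValueError):
    """A word has positive probability in p but zero in q."""


def kl_divergence(p: dict[str, float], q: dict[str, float]) -> float:
    """Kullback-Leibler divergence sum_w p(w) ln(p(w)/q(w)), in nats.

    Requires support(p) contained in support(q); the convention
    0 * ln(0/x) = 0 applies. Raises :class:`SupportError` naming the first
    offending word otherwise.
    """
    total = 0.0
    for w, pv in p.items():
        if pv <= 0.0:
            continue
        qv = q.get(w, 0.0)
        if qv <= 0.0:
            raise SupportError(
                f"word {w!r} has p={pv:g} but q=0; support(p) must be within support(q)"
            )
        total += pv * math.log(pv / qv)
    return max(total, 0.0)


@dataclass(frozen=True)
class EdgeWeight:
    child: str
    parent: str
    metric: str  # "ib" or "ic"
    value: float


def _distribution(profile: WordProfile, term: str, pseudocount: float,
                  vocabulary=None) -> dict[str, float]:
    if not profile.usable and pseudocount <= 0:
        raise ValueError(f"term {term} has an empty word profile; unusable for IB")
    if pseudocount > 0:
        vocab = vocabulary if vocabulary is not None else profile.counts.keys()
        total = profile.total + pseudocount * len(vocab)
        return {w: (profile.counts.get(w, 0) + pseudocount) / total for w in vocab}
    return profile.distribution()


def ib_edge_weight(
    graph: OntologyGraph,
    profiles: dict[str, WordProfile],
    child: str,
    parent: str,
    symmetric: bool = False,
    pseudocount: float = 0.0,
) -> EdgeWeight:
    """Semantic-context loss for collapsing `child` into `parent`."""
    if parent not in graph.parents(child):
        raise ValueError(f"({child}, {parent}) is not an IS_A edge")
    n_child = graph.descendant_count(child)
    n_parent = graph.descendant_count(parent)
    n_root = graph.descendant_count(graph.root)
    prior = n_child / n_root
    pi = n_child / n_parent

    vocab = set(profiles[child].counts) | set(profiles[parent].counts)
    p = _distribution(profiles[child], child, pseudocount, vocab)
    q = _distribution(profiles[parent], parent, pseudocount, vocab)
    if symmetric:
        m = {w: pi * p.get(w, 0.0) + (1.0 - pi) * q.get(w, 0.0) for w in vocab}
        djs = pi * kl_divergence(p, m) + (1.0 - pi) * kl_divergence(q, m)
    else:
        djs = pi * kl_divergence(p, q)
    return EdgeWeight(child=child, parent=parent, metric="ib", value=prior * djs)


def annotation_instances(graph: OntologyGraph) -> dict[str, int]:
    """Cumulative (gene, term) annotation-instance count per term.

    Each direct (gene, term) pair contributes once to every ancestor whose
    subtree contains the term; diamonds are not double-counted because the
    subtree is a set.
    """
    direct = {t: len(graph.direct_genes.get(t, ())) for t in graph.graph.nodes}
    return {
        t: sum(direct[s] for s in graph.subtree(t)) for t in graph.graph.nodes
    }


def information_content(
    term: str, graph: OntologyGraph, instances: dict[str, int] | None = None
) -> float:
    """IC(t) = -ln( instances(t) / instances(root) ), nonnegative."""
    if term not in graph.graph:
        raise KeyError(f"unknown term: {term}")
    if instances is None:
        instances = annotation_instances(graph)
    n_term = instances[term]
    n_root = instances[graph.root]
    if n_term == 0:
        raise ValueError(
            f"term {term} has zero annotation instances; it should have been pruned"
        )
    return -math.log(n_term / n_root)


def ic_edge_weight(
    parent: str,
    child: str,
    graph: OntologyGraph,
    instances: dict[str, int] | None = None,
) -> EdgeWeight:
    """Gene-information loss |IC(child) - IC(parent)| for an IS_A edge.

    With upward-propagated counts the child's IC can never be below the
    parent's, so this equals IC(child) - IC(parent).
    """
    if instances is None:
        instances = annotation_instances(graph)
    ic_c = information_content(child, graph, instances)
    ic_p = information_content(parent, graph, instances)
    return EdgeWeight(child=child, parent=parent, metric="ic",
                      value=abs(ic_c - ic_p))


@dataclass
class WeightedGraph:
    """Pruned ontology plus one information-loss weight per IS_A edge."""

    ontology: OntologyGraph
    metric: str
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def weight(self, child: str, parent: str) -> float:
        return self.weights[(child, parent)]

    def edge_values(self) -> list[float]:
        return [self.weights[e] for e in sorted(self.weights)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"child": c, "parent": p, "metric": self.metric, "weight": w}
            for (c, p), w in sorted(self.weights.items())
        ]
        return pd.DataFrame(rows, columns=["child", "parent", "metric", "weight"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def weight_all_edges(
    graph: OntologyGraph,
    metric: str = "ic",
    profiles: dict[str, WordProfile] | None = None,
    symmetric: bool = False,
    pseudocount: float = 0.0,
) -> WeightedGraph:
    """Weight every IS_A edge of a pruned, propagated graph under one metric."""
    metric = metric.lower()
    weights: dict[tuple[str, str], float] = {}
    failures: list[str] = []
    instances = annotation_instances(graph) if metric == "ic" else None
    for child, parent in graph.is_a_edges():
        try:
            if metric == "ic":
                ew = ic_edge_weight(parent, child, graph, instances)
            elif metric == "ib":
                if profiles is None:
                    raise ValueError("IB weighting requires word profiles")
                ew = ib_edge_weight(graph, profiles, child, parent,
                                    symmetric=symmetric, pseudocount=pseudocount)
            else:
                raise ValueError(f"unknown metric: {metric!r}")
            weights[(child, parent)] = ew.value
        except (ValueError, KeyError) as exc:
            failures.append(f"({child} -> {parent}): {exc}")
    if failures:
        raise ValueError(
            f"{len(failures)} edges could not be weighted:\n" + "\n".join(failures)
        )
    return WeightedGraph(ontology=graph, metric=metric, weights=weights)
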