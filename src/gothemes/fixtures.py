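"""Synthetic fixture generator: toy ontologies, annotations, corpora, and
benchmark files, so every pipeline stage runs and tests offline.

The generator emulates the input ecosystem at toy scale: a balanced b-ary
IS_A tree written as OBO, a GAF annotation file with planted gene modules
concentrated under designated subtrees plus scattered noise genes, a JSONL
document corpus whose per-term topics are Dirichlet perturbations of their
parent's topic (so semantic divergence shrinks with depth), and GMT/PPI
benchmark files with module-structured interaction density. Each artifact
draws from its own random stream spawned from the master seed, so
regenerating one never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np


@dataclass
class FixtureSpec:
    """Shape and noise parameters of one synthetic fixture set."""

    seed: int
    depth: int = 5  # number of levels including the root
    branching: int = 3
    n_genes: int = 500
    annotations_per_gene: int = 2
    vocab_size: int = 200
    doc_length: int = 30
    docs_per_term: int = 3
    concentration: float = 50.0  # child-topic fidelity to the parent topic
    n_modules: int = 2
    module_size: int = 10
    module_depth: int = 2  # level of the subtree roots the modules live under
    signature_terms: int = 3  # distinct leaves a planted module's genes share
    module_annotations_per_gene: int = 1  # annotations per planted-module gene
    module_scatter_rate: float = 0.10  # chance a module annotation lands on a
    # related (same-subtree, non-signature) term instead of a signature term
    local_annotations: bool = True  # a background gene's annotations stay
    # within one top-level branch (genes act in related processes)
    noise_rate: float = 0.05  # per-annotation chance of a uniform random leaf
    p_in: float = 0.5  # PPI edge probability within a planted module
    p_out: float = 0.02  # background PPI edge probability
    diamond: bool = False  # add one extra multi-parent edge

    def __post_init__(self) -> None:
        if self.depth < 2 or self.branching < 2:
            raise ValueError("need depth >= 2 and branching >= 2")
        if self.vocab_size < 10:
            raise ValueError("vocabulary must have at least 10 words")
        for p in (self.noise_rate, self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_in < self.p_out:
            import warnings

            warnings.warn("p_in < p_out: the PPI benchmark is uninformative",
                          stacklevel=2)
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("planted modules exceed the gene budget")
        if self.module_depth >= self.depth - 1:
            raise ValueError("module subtree roots must be internal, above leaves")

    # one independent stream per artifact (ontology/annotations/corpus/benchmark)
    def _rng(self, index: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[index])


def _term_id(i: int) -> str:
    return f"ST:{i:07d}"


@dataclass
class Ontology:
    """In-memory description of the generated tree (level-order ids)."""

    terms: list[str]
    names: dict[str, str]
    edges: list[tuple[str, str]]  # child -> parent
    levels: dict[str, int]
    children: dict[str, list[str]] = field(default_factory=dict)

    @property
    def root(self) -> str:
        return self.terms[0]

    def leaves(self) -> list[str]:
        non_leaf = {p for _, p in self.edges}
        return [t for t in self.terms if t not in non_leaf]

    def subtree_leaves(self, term: str) -> list[str]:
        out = []
        stack = [term]
        while stack:
            t = stack.pop()
            kids = self.children.get(t, [])
            if kids:
                stack.extend(kids)
            else:
                out.append(t)
        return sorted(out)


def _build_tree(spec: FixtureSpec) -> Ontology:
    terms, names, edges = [], {}, []
    levels: dict[str, int] = {}
    children: dict[str, list[str]] = {}
    counter = 1
    root = _term_id(counter)
    terms.append(root)
    names[root] = "biological process root"
    levels[root] = 0
    frontier = [root]
    for level in range(1, spec.depth):
        nxt = []
        for parent in frontier:
            for _ in range(spec.branching):
                counter += 1
                tid = _term_id(counter)
                terms.append(tid)
                names[tid] = f"synthetic process {counter}"
                edges.append((tid, parent))
                levels[tid] = level
                children.setdefault(parent, []).append(tid)
                nxt.append(tid)
        frontier = nxt
    onto = Ontology(terms=terms, names=names, edges=edges, levels=levels,
                    children=children)
    if spec.diamond:
        # give the last leaf a second parent: its parent's sibling
        leaf = terms[-1]
        parent = next(p for c, p in edges if c == leaf)
        gp = next(p for c, p in edges if c == parent)
        sibling = next(c for c in children[gp] if c != parent)
        onto.edges.append((leaf, sibling))
        onto.children.setdefault(sibling, []).append(leaf)
    return onto


def make_ontology(spec: FixtureSpec, path) -> Ontology:
    """Write a valid OBO 1.2 tree of the requested shape; returns the layout."""
    onto = _build_tree(spec)
    lines = [
        "format-version: 1.2",
        "default-namespace: biological_process",
        "ontology: synthetic",
        "",
    ]
    parent_map: dict[str, list[str]] = {}
    for child, parent in onto.edges:
        parent_map.setdefault(child, []).append(parent)
    for term in onto.terms:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {onto.names[term]}")
        lines.append("namespace: biological_process")
        for parent in parent_map.get(term, []):
            lines.append(f"is_a: {parent} ! {onto.names[parent]}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
    return onto


@dataclass
class Annotations:
    rows: list[tuple[str, str]]  # (gene, term)
    modules: dict[str, list[str]]  # module name -> gene ids
    module_roots: dict[str, str]  # module name -> subtree root term
    # background genes annotated wholly outside every planted subtree, usable
    # as off-theme noise when composing query lists
    off_module_genes: list[str] = field(default_factory=list)


def make_annotations(spec: FixtureSpec, onto: Ontology, path) -> Annotations:
    """Write a GAF 2.2 file with planted modules and scattered noise genes."""
    rng = spec._rng(1)
    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    leaves = onto.leaves()
    module_root_pool = sorted(
        t for t in onto.terms if onto.levels[t] == spec.module_depth
    )
    if not module_root_pool:
        raise ValueError(f"no internal terms at level {spec.module_depth}")
    # spread modules across distant top-level branches: round-robin over the
    # level-1 ancestor groups so two modules share a branch only when they must
    branch_of: dict[str, str] = {}
    for t in module_root_pool:
        anc = t
        while onto.levels[anc] > 1:
            anc = next(p for c, p in onto.edges if c == anc)
        branch_of[t] = anc
    groups: dict[str, list[str]] = {}
    for t in module_root_pool:
        groups.setdefault(branch_of[t], []).append(t)
    for members in groups.values():
        rng.shuffle(members)
    order = []
    pools = [groups[k] for k in sorted(groups)]
    while any(pools):
        for pool in pools:
            if pool:
                order.append(pool.pop())
    # more modules than subtrees -> subtree roots are reused (modules of the
    # same broad process with different member genes)
    picks = sorted(order[i % len(order)] for i in range(spec.n_modules))
    module_roots = {f"module{m + 1:02d}": t for m, t in enumerate(picks)}

    rows: list[tuple[str, str]] = []
    modules: dict[str, list[str]] = {}
    cursor = 0
    for mname, mroot in module_roots.items():
        member = genes[cursor: cursor + spec.module_size]
        cursor += spec.module_size
        modules[mname] = member
        # genes of one functional module are co-annotated to a handful of
        # signature terms, mirroring curators annotating pathway members
        # with the same specific terms
        subtree = onto.subtree_leaves(mroot)
        k = min(spec.signature_terms, len(subtree))
        # evenly spaced over the (sorted, hence sibling-grouped) leaf list so
        # every sub-branch carries signal
        if k == 1:
            pool = [subtree[0]]
        else:
            pool = [subtree[round(i * (len(subtree) - 1) / (k - 1))]
                    for i in range(k)]
        # a fixed share of module annotations lands on related non-signature
        # terms of the same subtree (fixed count, not per-annotation coin
        # flips, so every module carries the same amount of local spread)
        n_ann = len(member) * spec.module_annotations_per_gene
        n_scatter = round(spec.module_scatter_rate * n_ann)
        scatter_slots = set(
            rng.choice(n_ann, size=n_scatter, replace=False).tolist()
        )
        slot = 0
        for gi, g in enumerate(member):
            for a in range(spec.module_annotations_per_gene):
                if rng.random() < spec.noise_rate:
                    leaf = leaves[rng.integers(len(leaves))]
                elif slot in scatter_slots:
                    leaf = subtree[rng.integers(len(subtree))]
                else:
                    # deal signature terms round-robin so each is covered
                    leaf = pool[(gi + a) % len(pool)]
                rows.append((g, leaf))
                slot += 1
    branches = sorted({t for t in onto.terms if onto.levels[t] == 1})
    branch_leaves = {br: onto.subtree_leaves(br) for br in branches}
    for g in genes[cursor:]:
        if spec.local_annotations:
            pool = branch_leaves[branches[rng.integers(len(branches))]]
        else:
            pool = leaves
        for _ in range(spec.annotations_per_gene):
            if rng.random() < spec.noise_rate:
                rows.append((g, leaves[rng.integers(len(leaves))]))
            else:
                rows.append((g, pool[rng.integers(len(pool))]))

    planted_terms: set[str] = set()
    for mroot in module_roots.values():
        planted_terms.update(onto.subtree_leaves(mroot))
    by_gene: dict[str, set[str]] = {}
    for gene, term in rows:
        by_gene.setdefault(gene, set()).add(term)
    off_module = sorted(
        gene for gene in genes[cursor:]
        if by_gene.get(gene) and by_gene[gene].isdisjoint(planted_terms)
    )

    date = "20260101"
    gaf_lines = ["!gaf-version: 2.2"]
    for gene, term in rows:
        cols = [
            "SYN", gene, gene, "", term, "SYN:0000001", "IEA", "", "P",
            gene, "", "protein", "taxon:9606", date, "SYN", "", "",
        ]
        gaf_lines.append("\t".join(cols))
    Path(path).write_text("\n".join(gaf_lines) + "\n")
    return Annotations(rows=rows, modules=modules, module_roots=module_roots,
                       off_module_genes=off_module)


def make_corpus(spec: FixtureSpec, onto: Ontology, docs_path, map_path) -> None:
    """Write a JSONL corpus plus term->doc map.

    Each term's topic is a Dirichlet draw centred on its parent's topic with
    concentration `spec.concentration`; larger concentration makes children
    indistinguishable from parents, shrinking the semantic (IB) edge weights
    toward zero.
    """
    rng = spec._rng(2)
    vocab = [f"wv{i:04d}" for i in range(1, spec.vocab_size + 1)]
    eps = 0.05  # keeps every word's probability positive
    topics: dict[str, np.ndarray] = {
        onto.root: rng.dirichlet(np.ones(spec.vocab_size))
    }
    parent_of: dict[str, str] = {c: p for c, p in onto.edges}
    for term in onto.terms[1:]:
        parent_topic = topics[parent_of[term]]
        alpha = spec.concentration * parent_topic + eps
        topics[term] = rng.dirichlet(alpha)

    doc_lines, map_lines = [], []
    counter = 0
    for term in onto.terms:
        for _ in range(spec.docs_per_term):
            counter += 1
            doc_id = f"D{counter:06d}"
            words = rng.choice(vocab, size=spec.doc_length, p=topics[term])
            title = " ".join(words[:5])
            abstract = " ".join(words[5:])
            doc_lines.append(json.dumps(
                {"id": doc_id, "title": title, "abstract": abstract}))
            map_lines.append(f"{term}\t{doc_id}")
    Path(docs_path).write_text("\n".join(doc_lines) + "\n")
    Path(map_path).write_text("\n".join(map_lines) + "\n")


def make_benchmark(
    spec: FixtureSpec, ann: Annotations, gmt_path, ppi_path
) -> None:
    """Write GMT reference sets (the planted modules) and a module-structured
    PPI edge list (edge probability p_in within modules, p_out elsewhere)."""
    rng = spec._rng(3)
    gmt_lines = [
        "\t".join([name, "planted synthetic module"] + genes)
        for name, genes in ann.modules.items()
    ]
    Path(gmt_path).write_text("\n".join(gmt_lines) + "\n")

    genes = sorted({g for g, _ in ann.rows})
    in_module: dict[str, str] = {}
    for name, members in ann.modules.items():
        for g in members:
            in_module[g] = name
    edges = []
    for a, b in combinations(genes, 2):
        same = a in in_module and in_module.get(a) == in_module.get(b)
        p = spec.p_in if same else spec.p_out
        if rng.random() < p:
            edges.append((a, b))
    Path(ppi_path).write_text(
        "\n".join(f"{a}\t{b}" for a, b in edges) + ("\n" if edges else "")
    )


def calibration_spec(seed: int) -> FixtureSpec:
    """Standard-size conditions for null-model calibration studies: a depth-5,
    branching-3 ontology with 500 doubly-annotated genes."""
    return FixtureSpec(seed=seed)


def two_cluster_spec(seed: int) -> FixtureSpec:
    """Demonstration conditions for module recovery: two 10-gene clusters
    planted in distant top-level branches of a compact depth-4 ontology.

    Genes carry a single annotation; each cluster shares six signature leaves
    spread over its branch, with one in-branch scattered annotation per
    cluster. The compact graph makes random same-size gene sets span nearly
    the whole ontology, so the statistic separates branch-coherent clusters
    from their union sharply.
    """
    return FixtureSpec(
        seed=seed,
        depth=4,
        branching=3,
        module_depth=1,
        signature_terms=6,
        annotations_per_gene=1,
        module_annotations_per_gene=1,
        noise_rate=0.02,
        module_scatter_rate=0.10,
        local_annotations=False,
    )


def benchmark_spec(seed: int) -> FixtureSpec:
    """Discrimination-benchmark conditions: 50 planted modules whose genes
    are doubly annotated to overlapping signature pairs (curation redundancy)
    with a 30% chance of a stray annotation elsewhere (curation
    inconsistency), against singly-annotated background genes.

    The stray annotations inflate the plain Steiner statistic of coherent
    modules while the gene-sharing shortcuts of the augmented graph absorb
    them, so the augmented scheme discriminates coherent from random sets
    better — the behaviour the augmentation was designed for.
    """
    return FixtureSpec(
        seed=seed,
        depth=6,
        n_genes=600,
        n_modules=50,
        module_depth=1,
        signature_terms=4,
        annotations_per_gene=1,
        module_annotations_per_gene=2,
        noise_rate=0.30,
        module_scatter_rate=0.0,
        local_annotations=False,
    )


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    ontology: Ontology
    annotations: Annotations
    obo: Path
    gaf: Path
    docs: Path
    term_docs: Path
    gmt: Path
    ppi: Path
    manifest: Path


def generate(spec: FixtureSpec, outdir) -> FixtureBundle:
    """Generate the full fixture set into `outdir`; bit-identical per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("obo", "ontology.obo"), ("gaf", "annotations.gaf"),
        ("docs", "corpus.jsonl"), ("term_docs", "term_docs.tsv"),
        ("gmt", "reference_sets.gmt"), ("ppi", "ppi_edges.tsv"),
        ("manifest", "manifest.json"),
    ]}
    onto = make_ontology(spec, paths["obo"])
    ann = make_annotations(spec, onto, paths["gaf"])
    make_corpus(spec, onto, paths["docs"], paths["term_docs"])
    make_benchmark(spec, ann, paths["gmt"], paths["ppi"])
    manifest = {
        "seed": spec.seed,
        "modules": ann.modules,
        "module_roots": ann.module_roots,
        "n_terms": len(onto.terms),
        "n_genes": spec.n_genes,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return FixtureBundle(spec=spec, ontology=onto, annotations=ann, **paths)
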