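# Methods

This note records the model, the numerical and design choices, and what the
synthetic studies do and do not demonstrate.

## Ontology representation

Terms of one namespace (default `biological_process`) form a DAG with IS_A
edges stored child → parent; the namespace must have exactly one root, and
a cycle is a hard error naming the offending terms. Other relationship
types (part_of, regulates, …) are counted and ignored: the information-loss
metrics are defined on subsumption only, where collapsing a child into its
parent is a well-defined generalization. Gene and document associations
obey the true-path rule: `propagate` closes direct associations over
ancestors, so a term's cumulative set is the union over its subtree.
Propagation is idempotent and diamond-safe (sets, not counts).

`prune_unannotated` keeps exactly the terms whose cumulative gene set is
non-empty. A retained term whose parent was pruned is re-attached to the
removed parent's nearest retained ancestors, with the composite edge
carrying the minimum summed loss along the bypassed chain, so connectivity
to the root and path costs are both preserved.

The descendant count |t| includes the term itself: the root has
p(t_root) = 1 and leaves have |t| = 1, which keeps every ratio in the IB
weight well defined. Annotation instances are distinct (gene, term) pairs —
a gene annotated to the same term under two evidence codes counts once;
evidence codes are retained and can be filtered (e.g. IEA) at load time.

## Word profiles and the IB metric

Text preprocessing is tokenization on non-alphanumeric boundaries,
lowercasing, a fixed English stopword list, and the Porter (1980) stemmer
implemented in `_porter.py`; outputs are frozen in golden tests because
stored profiles are only comparable under one fixed pipeline.

A term's profile aggregates the name/description tokens of **every term in
its subtree** plus the title/abstract tokens of its cumulative documents.
Aggregating names along with documents is deliberate: it guarantees that a
child's profile support is contained in its parent's, which keeps
D_KL(child ‖ parent) finite without smoothing. (Propagating documents alone
cannot guarantee this — a child's name tokens need not appear anywhere in
the parent.) An optional pseudocount exists for robustness studies but
defaults to zero.

The IB edge weight follows the printed form of the divergence: a single
KL term weighted by π_i (not the symmetric two-sided variant); the
symmetric variant is available behind a flag for comparison. Natural
logarithms are used throughout both metrics, so all weights are in nats.

## Coherence statistic

The statistic of a gene set is the total weight of a Steiner tree spanning
the genes' **direct** annotation terms, with IS_A edges traversed as
undirected. Steiner trees are NP-hard; we use the Mehlhorn metric-closure
2-approximation, with nodes and edges inserted in sorted order so results
are deterministic. The exhaustive optimum (minimum spanning tree over every
connected superset of the terminals) exists only in tests and the
acceptance study, where it bounds the heuristic on graphs of ≤ 8 nodes.

Augmentation adds a shortcut d_ij = d_P5 / |g_ij| between every term pair
sharing at least one directly annotated gene; d_P5 is the 5th percentile
(linear interpolation) of the base edge-weight multiset, and sharing is
counted on direct annotations, matching the purpose of collapsing redundant
annotations of the same gene. Where a shortcut parallels an IS_A edge the
cheaper of the two is used. Both the null model and the summarizer gate
compute the statistic on the full pruned graph, so gate p-values are
calibrated against exactly the distribution that was sampled; confining the
tree to the summarizing term's subtree would decouple the two.

## Null model and p-values

Random gene sets are drawn uniformly without replacement from the genes
with ≥ 1 direct annotation in the pruned graph; the default design is 100
replicates per size on the grid {5, 10, …, 50} ∪ {60, 80, …, 200} (capped
at the universe size). Mean and variance are smoothed across sizes by
Nadaraya–Watson regression with the Gaussian kernel
exp(−(n_i − n)²/h), h = 10 — the kernel divides by h, not h², exactly as
the estimator is defined here. The p-value is the lower tail of the
Gaussian with the estimated moments; one-sided because coherence means
*less* loss than random. Queries outside the trained size range extrapolate
with a warning; a size whose kernel weights all underflow is an error
suggesting a larger bandwidth. Sub-minimum sets (below the smallest trained
size, default 5) are not testable and auto-pass the summarizer gate,
flagged `below_min_size`.

Calibration is verified empirically: on the standard synthetic graph the
p-values of 500 fresh random sets are uniform within KS ≈ 0.04–0.08. The
Gaussian is an approximation — the true statistic distribution is mildly
skewed — which is why the KS distance is small but not zero.

## Summarizer

Leaves merge into parents in ascending order of edge loss; a multi-parent
leaf goes to its cheapest parent; all ties break lexicographically on term
id, making the whole procedure deterministic. Two design points deserve
record:

* **Gate set.** A summarizing term annotates the genes of the subgraph
  beneath it, so the gate evaluates the parent's full remaining coverage:
  the query genes of its active subtree (itself, the merging child, and all
  other not-yet-frozen descendants). Genes reachable only through frozen
  lineages are excluded — freezing stops one lineage without stopping its
  siblings. Gating on the incremental union of already-merged children was
  considered and rejected: the union of two individually coherent clusters
  remains "coherent" all the way to the root under any sum-like statistic,
  and the procedure degenerates to one root module.
* **Labels.** A lineage often climbs through ancestors that contribute no
  new query genes before its first rejected merge, so the frozen head can
  sit above the informative term. Emitted modules are relabelled to the
  most specific term of the collapsed lineage whose subtree still covers
  every member gene (≥ 1 direct annotation each); deeper is more
  informative at zero extra loss. A module that can only be labelled by the
  root has, by definition (IC(root) = 0), no informative summary — the
  expected outcome when the input has no structure.

The global procedure stops when no merge candidate remains (every lineage
frozen or collapsed into a parentless head); remaining heads holding genes
are emitted. Termination is guaranteed (every step removes one active
term), every annotatable query gene appears in ≥ 1 module, and modules may
overlap through multi-annotated genes. Relaxing the cutoff accepts a
superset of merges at each decision point, so in practice it yields fewer,
larger modules; this is asserted on the demonstration fixture rather than
proven, since later gate sets depend on earlier decisions.

## Evaluation utilities

ROC analysis scores each labelled set by its null-model p-value, calls a
set coherent when p ≤ threshold, sweeps the observed p-values (plus 0 and
1) as thresholds, and integrates by trapezoid; the implementation is
cross-checked against scikit-learn on random scores. The PPI ratio is
R_PPI = I / C(g, 2), observed interactions over possible pairs — the
denominator is the count of unordered pairs, the only reading under which
the quantity is a ratio of observed to maximal interactions. The
cutoff sweep averages R_PPI over modules that actually faced the gate
(n ≥ 2 and not below the minimum testable size).

## Synthetic data: what it emulates, and what it does not

The generator emits a balanced b-ary IS_A tree (optionally with a diamond),
a GAF 2.2 annotation file, a JSONL corpus with a term→document map, GMT
reference sets, and a two-column PPI edge list — all parsed back through
the package's own readers, and bit-identical for a fixed seed (one
independent random stream per artifact).

Annotation structure: planted modules concentrate their genes'
annotations on a few *signature* leaves of a designated subtree
(curators annotate pathway members with the same specific terms), with a
fixed share scattered to related non-signature terms of the same subtree;
background genes annotate uniformly, or within one top-level branch when
`local_annotations` is on (genes act in related processes). Documents are
drawn from per-term multinomials in which a child's topic is a Dirichlet
perturbation of its parent's with concentration κ, so semantic divergence
shrinks with depth; sibling topics stay distinguishable at finite κ. PPI
edges appear with probability p_in within planted modules and p_out
elsewhere.

Three named condition sets are frozen as the package's study conditions:

* `calibration_spec` — depth 5, branching 3, 500 doubly-annotated genes;
  used for null-calibration and random-query studies. At this size a
  50-gene query is small relative to the ontology, the regime the method
  targets.
* `two_cluster_spec` — depth 4, branching 3, two 10-gene clusters planted
  in distant top-level branches, six signature leaves each, singly
  annotated, 10% in-branch scatter. The compact graph makes random
  same-size sets span nearly the whole ontology, which is what lets the
  union of the two clusters (plus two off-theme genes) fail the gate at the
  root while each cluster passes comfortably within its branch. Recovery
  of both clusters holds at the demonstration seed and at roughly 8 of 10
  seeds; the margins are a property of these conditions, not of the method
  at every scale.
* `benchmark_spec` — depth 6, 50 ten-gene modules over 600 genes; module
  genes carry two annotations drawn from overlapping signature pairs
  (annotation redundancy) with a 30% chance of a stray annotation anywhere
  (annotation inconsistency); background genes carry one. The strays
  inflate the plain Steiner cost of coherent modules while the augmented
  graph's same-gene shortcuts absorb them — so the augmented scheme's
  AUROC exceeds the plain scheme's (≈ 0.80–0.86 vs ≈ 0.68–0.80 across
  seeds), reproducing the qualitative ordering of the two schemes.

What passing these studies does **not** show: real GO topology (tangled
DAG, 30k terms, heavy-tailed annotation counts), real literature text,
identifier mapping, or evidence-code quality are all outside the synthetic
model; absolute AUROCs and recovery rates on real data will differ. The
studies demonstrate correctness of the machinery and the *direction* of
the methodological comparisons, not field performance.

## Problem sizes

Default study sizes were chosen so the full suite and the acceptance
script each run in a few minutes on one core: 50 oracle graphs of ≤ 8
nodes; 500 fresh sets for calibration; 50 module/random pairs for ROC; 10
replicate fixtures for the random-query and PPI-trend studies; null fits
of 60–100 replicates per size. All are parameters of the study functions
in `gothemes.experiments`.

## Known limitations

* Only IS_A edges are used; part_of/regulates relations are ignored (with
  a count), which understates connectivity for some namespaces.
* The Gaussian null is an approximation; extreme tail p-values (≪ 1e-6)
  should be read as "very small", not as exact frequencies.
* The merge procedure is greedy; it does not revisit a freeze even if a
  later merge elsewhere would have changed the landscape.
* obsolete-term alt_id resolution is limited to a warning list; gene
  identifiers are opaque case-sensitive strings with no symbol mapping.
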