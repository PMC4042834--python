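"""Benchmarking: ROC discrimination of coherent vs random gene sets, and the
within-module protein-protein interaction (PPI) density.

The ROC treats the null-model p-value as the classification score: a gene
set is called coherent when its p-value falls at or below the threshold, and
the threshold sweeps the observed p-values. The PPI ratio of a gene set is
R_PPI = I / C(g, 2) — observed interactions over the maximal possible pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .coherence import gene_set_statistic
from .null_model import NullModel
from .summarizer import summarize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledGeneSet:
    set_id: str
    genes: frozenset[str]
    label: str  # "coherent" or "random"


@dataclass(frozen=True)
class PPIRatioResult:
    g: int
    interactions: int
    ratio: float


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT file: one (name, description, genes...) record per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"GMT line needs >=3 columns: {line[:80]!r}")
            out.append((cols[0], cols[1], [g for g in cols[2:] if g]))
    return out


def read_ppi(path) -> set[frozenset[str]]:
    """Read an undirected PPI edge list.

    Accepts a plain two-column TSV, or a header-bearing table with BioGRID
    style 'Official Symbol Interactor A'/'B' columns. Self-loops and
    duplicate/reversed edges are collapsed.
    """
    with open(path) as fh:
        first = fh.readline()
    if "Interactor A" in first or first.lstrip("#").lower().startswith("gene"):
        frame = pd.read_csv(path, sep="\t", comment=None)
        frame.columns = [c.lstrip("#") for c in frame.columns]
        col_a = next(c for c in frame.columns if "A" in c or c.lower() == "gene1")
        col_b = next(c for c in frame.columns if "B" in c or c.lower() == "gene2")
        pairs = zip(frame[col_a].astype(str), frame[col_b].astype(str))
    else:
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                rows.append((a, b))
        pairs = rows
    return {frozenset((a, b)) for a, b in pairs if a != b}


def matched_random_sets(
    coherent: list[tuple[str, list[str]]], universe: list[str], seed: int
) -> list[LabeledGeneSet]:
    """Size-matched random comparator for each coherent set (paired design)."""
    rng = np.random.default_rng(seed)
    universe = sorted(universe)
    out = []
    for name, genes in coherent:
        draw = rng.choice(len(universe), size=len(genes), replace=False)
        out.append(
            LabeledGeneSet(
                set_id=f"{name}|random",
                genes=frozenset(universe[i] for i in draw),
                label="random",
            )
        )
    return out


def score_sets(labeled, graph, null: NullModel) -> pd.DataFrame:
    """p-value of each labeled set under the null model."""
    gene_index = graph.ontology.gene_index()
    rows = []
    for s in labeled:
        stat = gene_set_statistic(s.genes, graph, gene_index=gene_index)
        p = null.p_value(stat.n, stat.value)
        rows.append({"set_id": s.set_id, "label": s.label, "n": stat.n,
                     "y_s": stat.value, "p": p})
    return pd.DataFrame(rows)


def roc(scored: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """ROC curve and area from per-set p-values.

    A set is called coherent when p <= threshold; thresholds sweep the sorted
    distinct p-values plus {0, 1}. Area by the trapezoid rule over FPR.
    """
    labels = scored["label"].to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("ROC needs both coherent and random sets")
    p = scored["p"].to_numpy(dtype=float)
    pos = labels == "coherent"
    neg = ~pos
    thresholds = np.concatenate(([0.0], np.unique(p), [1.0]))
    tpr = [(p[pos] <= t).mean() for t in thresholds]
    fpr = [(p[neg] <= t).mean() for t in thresholds]
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    curve = curve.sort_values(["fpr", "tpr"]).reset_index(drop=True)
    area = float(np.trapezoid(curve["tpr"], curve["fpr"]))
    return curve, area


def ppi_ratio(genes, ppi: set[frozenset[str]]) -> PPIRatioResult:
    """Observed interactions over maximal possible pairs within a gene set."""
    genes = set(genes)
    g = len(genes)
    if g < 2:
        raise ValueError("PPI ratio needs at least 2 genes")
    interactions = sum(
        1 for a, b in combinations(sorted(genes), 2) if frozenset((a, b)) in ppi
    )
    max_pairs = g * (g - 1) // 2
    return PPIRatioResult(g=g, interactions=interactions,
                          ratio=interactions / max_pairs)


def cutoff_sweep(
    gene_list,
    wgraph,
    null: NullModel,
    cutoffs,
    ppi: set[frozenset[str]],
) -> pd.DataFrame:
    """Mean within-module PPI ratio (with standard error) per p-value cutoff.

    Only modules that actually faced the coherence gate contribute to the
    mean: fragments below the smallest testable size never passed any
    statistical test and would only add noise.
    """
    rows = []
    for cutoff in cutoffs:
        modules = summarize(gene_list, wgraph, null, p_cutoff=cutoff)
        ratios = [
            ppi_ratio(m.genes, ppi).ratio
            for m in modules
            if m.n >= 2 and not m.below_min_size
        ]
        if ratios:
            mean = float(np.mean(ratios))
            se = float(np.std(ratios, ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
        else:
            mean, se = float("nan"), float("nan")
        rows.append({"cutoff": cutoff, "n_modules": len(modules),
                     "n_scored": len(ratios), "mean_r_ppi": mean, "se": se})
    return pd.DataFrame(rows)
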