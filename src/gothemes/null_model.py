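"""Simulation-calibrated null model for the coherence statistic.

Random gene sets of each size on a grid are drawn from the annotated gene
universe and scored; a Nadaraya-Watson kernel regression then smooths the
per-size mean and variance,

    mu_hat(n)    = sum_i w_n(n_i) y_i / sum_i w_n(n_i)
    sigma2_hat(n)= sum_i w_n(n_i) (y_i - mu_hat(n))^2 / sum_i w_n(n_i)
    w_n(n_i)     = exp( -(1/h) (n_i - n)^2 ),

with bandwidth h = 10 by default. An observed statistic y for a set of size
n is converted to a one-sided lower-tail Gaussian p-value
Phi((y - mu_hat(n)) / sigma_hat(n)): a coherent set loses LESS information
than random sets of its size, so small statistics give small p-values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coherence import AugmentedGraph, gene_set_statistic

logger = logging.getLogger(__name__)

DEFAULT_BANDWIDTH = 10.0
# sizes 5..50 step 5, then 60..200 step 20
DEFAULT_SIZE_GRID = tuple(range(5, 51, 5)) + tuple(range(60, 201, 20))
DEFAULT_REPS = 100


@dataclass
class NullSampleSet:
    """Statistics of size-stratified random gene sets."""

    sizes: np.ndarray  # n_i per record
    values: np.ndarray  # y_i per record
    metric: str
    scheme: str
    seed: int
    size_grid: tuple[int, ...]
    reps: int

    def __len__(self) -> int:
        return len(self.sizes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.sizes, "y": self.values})


def sample_null(
    graph,
    sizes=DEFAULT_SIZE_GRID,
    reps: int = DEFAULT_REPS,
    scheme: str | None = None,
    seed: int = 0,
) -> NullSampleSet:
    """Draw `reps` uniform random gene sets per size and score each.

    Genes are drawn without replacement from the genes carrying at least one
    direct annotation in the pruned graph. Fully reproducible from `seed`.
    """
    if scheme is None:
        scheme = "augmented" if isinstance(graph, AugmentedGraph) else "plain"
    universe = graph.ontology.annotated_genes()
    sizes = tuple(int(s) for s in sizes)
    if max(sizes) > len(universe):
        raise ValueError(
            f"requested size {max(sizes)} exceeds the annotated universe "
            f"({len(universe)} genes)"
        )
    gene_index = graph.ontology.gene_index()
    rng = np.random.default_rng(seed)
    ns, ys = [], []
    for size in sizes:
        for _ in range(reps):
            draw = rng.choice(len(universe), size=size, replace=False)
            genes = [universe[i] for i in draw]
            stat = gene_set_statistic(genes, graph, scheme, gene_index)
            ns.append(size)
            ys.append(stat.value)
    return NullSampleSet(
        sizes=np.asarray(ns, dtype=float),
        values=np.asarray(ys, dtype=float),
        metric=graph.metric,
        scheme=scheme,
        seed=seed,
        size_grid=sizes,
        reps=reps,
    )


def nw_estimate(samples: NullSampleSet, n: float,
                h: float = DEFAULT_BANDWIDTH) -> tuple[float, float]:
    """Nadaraya-Watson mean and variance of the null statistic at size n."""
    if len(samples) == 0:
        raise ValueError("empty null sample set")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    w = np.exp(-((samples.sizes - n) ** 2) / h)
    wsum = w.sum()
    if wsum == 0.0:
        raise ValueError(
            f"all kernel weights underflow to zero at n={n}; use a larger bandwidth"
        )
    mu = float(np.dot(w, samples.values) / wsum)
    sigma2 = float(np.dot(w, (samples.values - mu) ** 2) / wsum)
    return mu, sigma2


@dataclass
class NullModel:
    """Fitted size-conditional Gaussian null for one graph/metric/scheme."""

    samples: NullSampleSet
    h: float = DEFAULT_BANDWIDTH
    _cache: dict[float, tuple[float, float]] = field(default_factory=dict, repr=False)

    @property
    def min_size(self) -> int:
        return min(self.samples.size_grid)

    @property
    def max_size(self) -> int:
        return max(self.samples.size_grid)

    def estimate(self, n: float) -> tuple[float, float]:
        key = float(n)
        if key not in self._cache:
            if n < self.min_size or n > self.max_size:
                warnings.warn(
                    f"size {n} is outside the trained grid "
                    f"[{self.min_size}, {self.max_size}]; extrapolating",
                    stacklevel=2,
                )
            self._cache[key] = nw_estimate(self.samples, n, self.h)
        return self._cache[key]

    def p_value(self, n: float, y: float) -> float:
        """Lower-tail Gaussian p-value of statistic y at set size n."""
        mu, sigma2 = self.estimate(n)
        if sigma2 <= 0.0:
            raise ValueError(f"null variance at n={n} is zero; p-value undefined")
        return float(norm.cdf((y - mu) / np.sqrt(sigma2)))


def fit_null(
    graph,
    sizes=DEFAULT_SIZE_GRID,
    reps: int = DEFAULT_REPS,
    scheme: str | None = None,
    seed: int = 0,
    h: float = DEFAULT_BANDWIDTH,
) -> NullModel:
    """Sample the null and wrap it in a :class:`NullModel`."""
    return NullModel(samples=sample_null(graph, sizes, reps, scheme, seed), h=h)


def save_null(model: NullModel, tsv_path, json_path) -> None:
    """Persist the sample table (TSV) and parameters (JSON sidecar)."""
    model.samples.to_frame().to_csv(tsv_path, sep="\t", index=False)
    meta = {
        "metric": model.samples.metric,
        "scheme": model.samples.scheme,
        "seed": model.samples.seed,
        "size_grid": list(model.samples.size_grid),
        "reps": model.samples.reps,
        "h": model.h,
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def load_null(tsv_path, json_path) -> NullModel:
    frame = pd.read_csv(tsv_path, sep="\t")
    with open(json_path) as fh:
        meta = json.load(fh)
    samples = NullSampleSet(
        sizes=frame["n"].to_numpy(dtype=float),
        values=frame["y"].to_numpy(dtype=float),
        metric=meta["metric"],
        scheme=meta["scheme"],
        seed=meta["seed"],
        size_grid=tuple(meta["size_grid"]),
        reps=meta["reps"],
    )
    return NullModel(samples=samples, h=meta["h"])
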