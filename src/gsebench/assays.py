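"""Benchmark assays: significance behavior, type-I error, set-size effects,
runtime, and cross-method aggregation.

These are the controlled experiments run on top of the enrichment methods:

* :func:`type_one_error_assay` — shuffle the binary sample labels many times
  and record, per shuffle, the fraction of gene sets a method calls
  significant at nominal p < alpha. On null data this should hover around
  alpha for a well-calibrated method.
* :func:`random_set_size_assay` — run a method on random gene sets of defined
  sizes (default 5..500) with the true labels, recording the significant
  fraction per size. Self-contained statistics grow with set size; a size
  trend on random sets flags set-size dependency.
* :func:`aggregate_compare` — median/IQR of relative relevance scores by
  method or by hypothesis type, with pairwise Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EARanking, ExpressionDataset, GeneSetCollection
from .methods import get_method, permuted_indicators, run_method
from .relevance import RelevanceResult
from .simulate import sample_random_sets

logger = logging.getLogger(__name__)

__all__ = [
    "AssayResult",
    "significance_fraction",
    "type_one_error_assay",
    "random_set_size_assay",
    "runtime_profile",
    "aggregate_compare",
    "DEFAULT_RANDOM_SET_SIZES",
]

#: Default gene set sizes probed by the random-set assay.
DEFAULT_RANDOM_SET_SIZES = (5, 10, 25, 50, 100, 250, 500)


@dataclass
class AssayResult:
    """Tidy per-replicate output of one assay for one method."""

    method: str
    assay: str
    table: pd.DataFrame  # columns depend on the assay; always has 'fraction'
    params: dict = field(default_factory=dict)

    @property
    def mean_fraction(self) -> float:
        return float(self.table["fraction"].mean())

    @property
    def sd_fraction(self) -> float:
        return float(self.table["fraction"].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        keys = [c for c in ("size",) if c in self.table.columns]
        if keys:
            g = self.table.groupby(keys)["fraction"]
            return g.agg(["mean", "std"]).reset_index()
        return pd.DataFrame(
            {"mean": [self.mean_fraction], "std": [self.sd_fraction]}
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def significance_fraction(
    ranking: EARanking, alpha: float = 0.05, adjusted: bool = False
) -> float:
    """Fraction of gene sets with (adjusted) p below ``alpha``."""
    col = "adj_p" if adjusted else "p_value"
    p = ranking.table[col].to_numpy(dtype=float)
    if p.size == 0:
        raise ValueError("empty ranking")
    return float(np.mean(p < alpha))


def type_one_error_assay(
    method: str,
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    method_params: dict | None = None,
) -> AssayResult:
    """Per-shuffle significant fractions under randomized sample labels.

    Each of ``n_shuffles`` shuffles of the group labels (within blocks when
    present) re-runs the method and records the fraction of sets with nominal
    p < ``alpha``. Permutation methods receive a fresh seed per shuffle drawn
    from the assay seed.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    params = dict(method_params or {})
    spec = get_method(method)
    rng = np.random.default_rng(seed)
    ind = dataset.group_indicator()
    g1, g2 = dataset.group_levels
    perms = permuted_indicators(ind, n_shuffles, rng, dataset.blocks)
    fractions = np.empty(n_shuffles)
    for i in range(n_shuffles):
        labels = [g2 if v else g1 for v in perms[i]]
        params_i = (
            {**params, "seed": int(rng.integers(2**31 - 1))}
            if spec.needs_permutations
            else params
        )
        ranking = run_method(method, dataset.with_groups(labels), collection, **params_i)
        fractions[i] = significance_fraction(ranking, alpha=alpha, adjusted=False)
    table = pd.DataFrame({"shuffle": np.arange(n_shuffles), "fraction": fractions})
    return AssayResult(
        method=method,
        assay="type_one_error",
        table=table,
        params={"n_shuffles": n_shuffles, "alpha": alpha, "seed": seed, **params},
    )


def random_set_size_assay(
    method: str,
    dataset: ExpressionDataset,
    sizes: Sequence[int] = DEFAULT_RANDOM_SET_SIZES,
    n_sets: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    method_params: dict | None = None,
) -> AssayResult:
    """Significant fraction of random gene sets per defined set size.

    For each size ``s``, ``n_sets`` uniform random sets are drawn from the
    dataset's gene universe and the method runs once with the *true* labels;
    recorded is the fraction of sets with nominal p < ``alpha``.
    """
    sizes = list(sizes)
    if max(sizes) > dataset.n_genes:
        raise ValueError(
            f"max set size {max(sizes)} exceeds universe of {dataset.n_genes} genes"
        )
    params = dict(method_params or {})
    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        coll = sample_random_sets(
            dataset.gene_ids, size=s, count=n_sets, seed=int(rng.integers(2**31 - 1))
        )
        params_i = dict(params)
        if get_method(method).needs_permutations:
            params_i.setdefault("seed", int(rng.integers(2**31 - 1)))
        ranking = run_method(method, dataset, coll, **params_i)
        rows.append({"size": s, "fraction": significance_fraction(ranking, alpha=alpha)})
    table = pd.DataFrame(rows)
    return AssayResult(
        method=method,
        assay="random_set_size",
        table=table,
        params={"sizes": sizes, "n_sets": n_sets, "alpha": alpha, "seed": seed, **params},
    )


def runtime_profile(
    method: str,
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    method_params: dict | None = None,
) -> float:
    """Wall-clock seconds for a single method run (reported, never asserted)."""
    start = time.perf_counter()
    run_method(method, dataset, collection, **(method_params or {}))
    return time.perf_counter() - start


def aggregate_compare(
    results: Sequence[RelevanceResult], grouping: str = "hypothesis_type"
) -> pd.DataFrame:
    """Compare relative relevance scores between groups of results.

    ``grouping`` is ``"hypothesis_type"`` (competitive vs self-contained) or
    ``"method"``. Returns one row per group with the median and IQR of
    ``X_bar`` plus two-sided Wilcoxon rank-sum p-values against every other
    group (columns ``p_vs_<group>``).
    """
    if grouping not in ("hypothesis_type", "method"):
        raise ValueError(f"unknown grouping {grouping!r}")
    key = (
        (lambda r: r.hypothesis.value) if grouping == "hypothesis_type" else (lambda r: r.method)
    )
    by_group: dict[str, list[float]] = {}
    for r in results:
        by_group.setdefault(key(r), []).append(r.x_bar)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups to compare")
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 results")
    groups = sorted(by_group)
    rows = []
    for g in groups:
        vals = np.asarray(by_group[g])
        row = {
            "group": g,
            "n": vals.size,
            "median_x_bar": float(np.median(vals)),
            "iqr_low": float(np.percentile(vals, 25)),
            "iqr_high": float(np.percentile(vals, 75)),
        }
        for other in groups:
            if other == g:
                continue
            stat = stats.mannwhitneyu(
                by_group[g], by_group[other], alternative="two-sided"
            )
            row[f"p_vs_{other}"] = float(stat.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
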