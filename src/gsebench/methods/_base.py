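"""Shared machinery for enrichment methods.

All methods implement one contract: dataset + gene set collection in,
:class:`~gsebench.datatypes.EARanking` out. This module provides

* the method registry (:func:`register_method`, :func:`get_method`,
  :func:`run_method`),
* the empirical p-value convention ``p = (b + 1) / (B + 1)``,
* the sample-label permutation engine (block-respecting), and
* deterministic assembly of the output ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ..datatypes import EARanking, ExpressionDataset, GeneSetCollection, Hypothesis
from ..genestats import (
    _one_sample_kernel,
    _paired_diffs,
    bh_adjust,
    moderated_t_matrix,
    ordinary_t_matrix,
    prepare_log_matrix,
    s2n_matrix,
    sam_t_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MethodSpec",
    "register_method",
    "get_method",
    "list_methods",
    "run_method",
    "permutation_pvalue",
    "permuted_indicators",
    "assemble_ranking",
]

#: Default number of sample-label permutations for permutation-based methods.
DEFAULT_N_PERM = 1000


@dataclass
class MethodSpec:
    """Registry entry describing one enrichment method."""

    name: str
    hypothesis: Hypothesis
    needs_permutations: bool
    runner: Callable[..., EARanking] | None
    defaults: dict = field(default_factory=dict)
    description: str = ""

    @property
    def implemented(self) -> bool:
        return self.runner is not None


_REGISTRY: dict[str, MethodSpec] = {}


def register_method(spec: MethodSpec) -> MethodSpec:
    if spec.name in _REGISTRY:
        raise ValueError(f"method {spec.name!r} already registered")
    _REGISTRY[spec.name] = spec
    return spec


def get_method(name: str) -> MethodSpec:
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown method {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def list_methods(implemented_only: bool = False) -> list[str]:
    return [n for n, s in _REGISTRY.items() if s.implemented or not implemented_only]


def run_method(
    name: str,
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    **params,
) -> EARanking:
    """Run a registered method and return its gene set ranking.

    Count/TPM datasets are variance-stabilized first; the collection is
    intersected with the dataset's measured genes; genes with zero variance
    across all samples are dropped with a warning before any statistics are
    computed.
    """
    spec = get_method(name)
    if not spec.implemented:
        raise NotImplementedError(
            f"method {spec.name!r} is a registry stub; plug in an implementation"
        )
    ds = prepare_log_matrix(dataset)
    var = ds.matrix.var(axis=1)
    if np.any(var <= 0):
        keep = var > 0
        logger.warning(
            "%d constant gene(s) removed before running %s", int((~keep).sum()), spec.name
        )
        ds = ExpressionDataset(
            matrix=ds.matrix[keep],
            gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
            sample_ids=ds.sample_ids,
            groups=ds.groups,
            blocks=ds.blocks,
            kind=ds.kind,
            name=ds.name,
        )
    sub = collection.intersect_universe(ds.gene_ids)
    if len(sub) == 0:
        raise ValueError("no gene set survives intersection with the dataset universe")
    kwargs = {**spec.defaults, **params}
    ranking = spec.runner(ds, sub, **kwargs)
    ranking.dataset = dataset.name
    return ranking


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def permutation_pvalue(
    observed: float, null_values: Sequence[float] | np.ndarray, tail: str = "upper"
) -> float:
    """Empirical p-value ``(b + 1) / (B + 1)``, never exactly zero.

    ``b`` counts null values at least as extreme as ``observed`` under the
    stated tail (``upper``, ``lower``, or ``two_sided`` on absolute values).
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    if tail == "upper":
        b = int(np.sum(null_values >= observed))
    elif tail == "lower":
        b = int(np.sum(null_values <= observed))
    elif tail == "two_sided":
        b = int(np.sum(np.abs(null_values) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (b + 1) / (null_values.size + 1)


def permuted_indicators(
    ind: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    blocks: Sequence[str] | None = None,
) -> np.ndarray:
    """``n_perm`` shuffled copies of a binary group indicator.

    Without blocks, labels are permuted freely across samples; with blocks,
    labels are permuted within each block only, preserving pairing/batch
    structure.
    """
    ind = np.asarray(ind)
    out = np.empty((n_perm, ind.size), dtype=ind.dtype)
    if blocks is None:
        for i in range(n_perm):
            out[i] = rng.permutation(ind)
    else:
        blocks_arr = np.asarray(blocks)
        idx_by_block = [np.where(blocks_arr == b)[0] for b in dict.fromkeys(blocks)]
        for i in range(n_perm):
            perm = ind.copy()
            for idx in idx_by_block:
                perm[idx] = rng.permutation(ind[idx])
            out[i] = perm
    return out


def make_stat_fn(statistic: str, blocks: Sequence[str] | None):
    """A function ``(matrix, ind) -> per-gene statistic values``.

    Chooses the unpaired kernel, or the paired one when blocks are present.
    Zero-variance genes come back as ``nan``; callers run after the constant
    genes are removed, so in practice values are finite.
    """
    if blocks is not None:
        def paired(matrix: np.ndarray, ind: np.ndarray) -> np.ndarray:
            diffs = _paired_diffs(matrix, ind, list(blocks))
            values, _, _, _ = _one_sample_kernel(diffs, statistic)
            return values

        return paired
    if statistic == "ordinary_t":
        return lambda m, ind: ordinary_t_matrix(m, ind)[0]
    if statistic == "moderated_t":
        return lambda m, ind: moderated_t_matrix(m, ind)[0]
    if statistic == "sam_t":
        return lambda m, ind: sam_t_matrix(m, ind)[0]
    if statistic == "s2n":
        return lambda m, ind: s2n_matrix(m, ind)[0]
    raise ValueError(f"no kernel for statistic {statistic!r}")


def membership_matrix(
    collection: GeneSetCollection, gene_ids: Sequence[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Boolean sets x genes matrix aligned to ``gene_ids`` order."""
    index = {g: i for i, g in enumerate(gene_ids)}
    set_ids = list(collection.sets)
    mat = np.zeros((len(set_ids), len(gene_ids)), dtype=bool)
    for row, sid in enumerate(set_ids):
        for g in collection.sets[sid]:
            j = index.get(g)
            if j is not None:
                mat[row, j] = True
    sizes = mat.sum(axis=1)
    return mat, set_ids, sizes


# ---------------------------------------------------------------------------
# ranking assembly
# ---------------------------------------------------------------------------

def assemble_ranking(
    set_ids: list[str],
    sizes: Sequence[int],
    statistics: np.ndarray,
    p_values: np.ndarray,
    method: str,
    hypothesis: Hypothesis,
    dataset: str = "",
) -> EARanking:
    """Build a deterministic :class:`EARanking` from per-set results.

    Ranks: ascending p-value, ties broken by descending absolute statistic,
    then lexicographic set id. Weights: tie-aware rank weights
    ``w = 1 - P(p' <= p)`` computed from the p-value column.
    """
    from ..relevance import ranks_to_weights  # deferred to avoid an import cycle

    statistics = np.asarray(statistics, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    n = len(set_ids)
    if not (len(sizes) == statistics.size == p_values.size == n):
        raise ValueError("per-set arrays must have equal length")
    order = sorted(
        range(n), key=lambda i: (p_values[i], -abs(statistics[i]), set_ids[i])
    )
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    weights = ranks_to_weights(p_values, orientation="smaller")
    table = pd.DataFrame(
        {
            "set_id": set_ids,
            "size": np.asarray(sizes, dtype=int),
            "statistic": statistics,
            "p_value": p_values,
            "adj_p": bh_adjust(p_values),
            "rank": rank,
            "weight": weights,
        }
    ).sort_values("rank", kind="stable")
    return EARanking(table=table, method=method, hypothesis=hypothesis, dataset=dataset)
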