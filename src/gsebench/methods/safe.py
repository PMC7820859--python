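"""SAFE: significance analysis of function and expression.

A two-layer permutation framework: a user-chosen *local* (per-gene) statistic
is condensed by a *global* (per-set) statistic, and significance comes from
recomputing both layers under sample-label permutations. The default pairing
is the Student t locally and the Wilcoxon rank sum of the set genes'
|t| against the non-set genes globally — a competitive test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..datatypes import EARanking, ExpressionDataset, GeneSetCollection, Hypothesis
from ._base import (
    DEFAULT_N_PERM,
    assemble_ranking,
    make_stat_fn,
    membership_matrix,
    permuted_indicators,
)

__all__ = ["run_safe", "GLOBAL_STATS"]


def _wilcoxon_rank_sums(local_abs: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Rank-sum W of each set's genes' |local statistic| among all genes.

    Midranks are used for ties, so the degenerate all-equal case sits exactly
    at its expectation ``m (N + 1) / 2``.
    """
    ranks = stats.rankdata(local_abs, method="average")
    return membership @ ranks


GLOBAL_STATS = {"wilcoxon": _wilcoxon_rank_sums}


def run_safe(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    local_stat: str = "ordinary_t",
    global_stat: str = "wilcoxon",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> EARanking:
    """SAFE ranking with permutation p-values (upper tail of the global stat).

    ``local_stat`` is any registered per-gene statistic (``ordinary_t``,
    ``moderated_t``, ``sam_t``, ``s2n``) — swapping it changes only the local
    layer. ``global_stat`` must be registered in :data:`GLOBAL_STATS`. A set
    equal to the entire universe has no background and is an error.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    try:
        global_fn = GLOBAL_STATS[global_stat]
    except KeyError:
        raise ValueError(
            f"unknown global statistic {global_stat!r}; registered: {sorted(GLOBAL_STATS)}"
        ) from None
    ds = dataset
    mem, set_ids, sizes = membership_matrix(collection, ds.gene_ids)
    if np.any(sizes == len(ds.gene_ids)):
        raise ValueError("a set spanning the entire universe has no competitive background")
    stat_fn = make_stat_fn(local_stat, ds.blocks)
    ind = ds.group_indicator()

    observed = global_fn(np.abs(stat_fn(ds.matrix, ind)), mem)

    rng = np.random.default_rng(seed)
    perms = permuted_indicators(ind, n_perm, rng, ds.blocks)
    exceed = np.zeros(len(set_ids), dtype=int)
    for i in range(n_perm):
        null = global_fn(np.abs(stat_fn(ds.matrix, perms[i])), mem)
        exceed += null >= observed
    p = (exceed + 1) / (n_perm + 1)

    return assemble_ranking(
        set_ids=set_ids,
        sizes=sizes,
        statistics=observed,
        p_values=p,
        method="safe",
        hypothesis=Hypothesis.COMPETITIVE,
    )
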