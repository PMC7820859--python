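"""SAMGS: a self-contained gene set test on SAM statistics.

The set statistic is the sum over the set's genes of the squared SAM
(regularized t) statistic — a T^2-like measure of total differential
expression inside the set, with no reference to genes outside it.
Significance is by sample-label permutation, upper tail. Being
self-contained, the statistic can only grow as a set gains genes, which is
the root of the method's gene-set-size dependency.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import EARanking, ExpressionDataset, GeneSetCollection, Hypothesis
from ._base import (
    DEFAULT_N_PERM,
    assemble_ranking,
    make_stat_fn,
    membership_matrix,
    permuted_indicators,
)

__all__ = ["run_samgs"]


def run_samgs(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> EARanking:
    """SAMGS ranking with permutation p-values (upper tail)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ds = dataset
    mem, set_ids, sizes = membership_matrix(collection, ds.gene_ids)
    memf = mem.astype(float)
    stat_fn = make_stat_fn("sam_t", ds.blocks)
    ind = ds.group_indicator()

    observed = memf @ stat_fn(ds.matrix, ind) ** 2

    rng = np.random.default_rng(seed)
    perms = permuted_indicators(ind, n_perm, rng, ds.blocks)
    exceed = np.zeros(len(set_ids), dtype=int)
    for i in range(n_perm):
        null = memf @ stat_fn(ds.matrix, perms[i]) ** 2
        exceed += null >= observed
    p = (exceed + 1) / (n_perm + 1)

    return assemble_ranking(
        set_ids=set_ids,
        sizes=sizes,
        statistics=observed,
        p_values=p,
        method="samgs",
        hypothesis=Hypothesis.SELF_CONTAINED,
    )
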