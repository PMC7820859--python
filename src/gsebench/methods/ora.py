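"""Over-representation analysis (ORA).

Fisher's exact / hypergeometric test on the overlap between a list of
differentially expressed (DE) genes and each gene set, against the universe
of measured genes. Competitive: the null says genes in the set are DE no more
often than genes outside it.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from ..datatypes import EARanking, ExpressionDataset, GeneSetCollection, Hypothesis
from ..genestats import call_de_genes, gene_level_stats
from ._base import assemble_ranking

logger = logging.getLogger(__name__)

__all__ = ["run_ora", "ora_from_dataset"]


def run_ora(
    de_genes: set[str],
    universe: set[str] | list[str],
    collection: GeneSetCollection,
) -> EARanking:
    """Hypergeometric upper-tail test of DE/set overlap for every gene set.

    For a set with ``m`` genes in a universe of ``N`` genes of which ``K``
    are DE, the p-value is ``P(X >= k)`` for the observed overlap ``k`` under
    the hypergeometric distribution. The reported statistic is the overlap
    count. Sets are intersected with the universe first; sets emptied by the
    intersection are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    de_genes = set(de_genes)
    if not de_genes:
        raise ValueError(
            "empty DE gene list; relax the DE criterion (e.g. nominal p-values) "
            "or supply a fallback gene list"
        )
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    sub = collection.intersect_universe(universe)
    if len(sub) == 0:
        raise ValueError("no gene set overlaps the universe")

    N = len(universe)
    K = len(de_genes)
    set_ids, sizes, ks, ps = [], [], [], []
    for sid, genes in sub.sets.items():
        m = len(genes)
        k = len(de_genes.intersection(genes))
        # P(X >= k) = survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, N, K, m))
        set_ids.append(sid)
        sizes.append(m)
        ks.append(k)
        ps.append(min(p, 1.0))
    return assemble_ranking(
        set_ids=set_ids,
        sizes=sizes,
        statistics=np.asarray(ks, dtype=float),
        p_values=np.asarray(ps, dtype=float),
        method="ora",
        hypothesis=Hypothesis.COMPETITIVE,
    )


def ora_from_dataset(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    statistic: str = "moderated_t",
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    criterion: str = "both",
    fallback_nominal: bool = True,
) -> EARanking:
    """Registry adapter: derive the DE gene list from the dataset, then test.

    The DE list uses the standard thresholds (|log2 FC| > 1, BH-adjusted
    p < 0.05). If nothing passes and ``fallback_nominal`` is set, the list
    falls back to nominal p < 0.05 (p-only) with a warning, so ORA remains
    applicable on weak-signal datasets. Blocks are honored through the paired
    gene statistics; ORA itself has no permutation step.
    """
    stats_vec = gene_level_stats(dataset, statistic=statistic)
    de = call_de_genes(
        stats_vec,
        lfc_threshold=lfc_threshold,
        fdr_threshold=fdr_threshold,
        criterion=criterion,
    )
    if not de and fallback_nominal:
        logger.info(
            "no gene passes |logFC|>%.2g & FDR<%.2g; falling back to nominal p<%.2g",
            lfc_threshold,
            fdr_threshold,
            fdr_threshold,
        )
        de = call_de_genes(
            stats_vec, fdr_threshold=fdr_threshold, criterion="p_only", adjusted=False
        )
    universe = set(stats_vec.gene_ids) - stats_vec.flagged
    return run_ora(de, universe, collection)
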