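"""Phenotype-relevance scoring of gene set rankings.

A method's ranking of ``N`` gene sets is compared against an a-priori
relevance ranking with scores ``S_p >= 0`` per set. Ranks are turned into
weights: the set at absolute rank ``r`` gets ``w = 1 - r/N`` (so the
top-ranked set gets close to 1, the bottom 0); with ties, the relative rank
is the fraction of sets whose ranking statistic is at least as extreme. The
relevance score of the ranking is the weight/score dot product

    ``X = sum_i w(i) S_p(i)``

normalized by the theoretical optimum ``O_p`` (the score of the ranking that
orders sets exactly by ``S_p``) to give ``X_bar = X / O_p`` in [0, 1],
comparable across datasets and collections. Two empirical nulls calibrate an
observed score: random rankings of the same sets, and rankings produced by
re-running the method on label-permuted data (which preserves ranking
dependencies induced by overlapping sets).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as _all_permutations

import numpy as np

from .datatypes import (
    EARanking,
    ExpressionDataset,
    GeneSetCollection,
    Hypothesis,
    RelevanceRanking,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RelevanceResult",
    "ranks_to_weights",
    "relevance_score",
    "optimal_and_relative",
    "random_ranking_pvalue",
    "label_permutation_pvalue",
    "evaluate_relevance",
]

#: Below this many orderings, the random-ranking null is enumerated exactly.
EXHAUSTIVE_LIMIT = 10_000


def ranks_to_weights(statistics: np.ndarray, orientation: str) -> np.ndarray:
    """Tie-aware rank weights ``w = 1 - r*`` for a ranking statistic vector.

    ``orientation`` declares what "extreme" means: ``"smaller"`` for p-values
    (small is top-ranked) or ``"larger"`` for scores. ``r*`` is the fraction
    of sets with a statistic at least as extreme, which reduces to the
    ordinary relative rank ``r_A / N`` when the statistics are tie-free; with
    all statistics equal, every weight is 0.
    """
    values = np.asarray(statistics, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one statistic")
    if np.any(~np.isfinite(values)):
        raise ValueError("ranking statistics must be finite")
    n = values.size
    srt = np.sort(values)
    if orientation == "smaller":
        at_least = np.searchsorted(srt, values, side="right")
    elif orientation == "larger":
        at_least = n - np.searchsorted(srt, values, side="left")
    else:
        raise ValueError(f"orientation must be 'smaller' or 'larger', got {orientation!r}")
    return 1.0 - at_least / n


def _align(
    ranking: EARanking, relevance: RelevanceRanking
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Shared set ids, the ranking's weights recomputed on the shared subset,
    and the aligned relevance scores."""
    shared = [sid for sid in ranking.set_ids if sid in relevance.scores]
    n_only_rank = ranking.n_sets - len(shared)
    n_only_rel = len(relevance) - len(shared)
    if not shared:
        raise ValueError("ranking and relevance ranking share no gene sets")
    if n_only_rank or n_only_rel:
        logger.info(
            "relevance scoring on %d shared sets (%d ranking-only, %d relevance-only dropped)",
            len(shared),
            n_only_rank,
            n_only_rel,
        )
    tab = ranking.table.set_index("set_id").loc[shared]
    weights = ranks_to_weights(tab["p_value"].to_numpy(dtype=float), orientation="smaller")
    scores = np.array([relevance.scores[s] for s in shared])
    return shared, weights, scores


def _apply_truncation(weights: np.ndarray, top_fraction: float | None) -> np.ndarray:
    """Zero out weights of sets ranked below the top ``top_fraction``.

    Restricting evaluation to e.g. the top 20% of a ranking keeps the weights
    of the surviving sets unchanged and zeroes the rest.
    """
    if top_fraction is None:
        return weights
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    cut = 1.0 - top_fraction
    return np.where(weights >= cut, weights, 0.0)


def relevance_score(
    ranking: EARanking,
    relevance: RelevanceRanking,
    top_fraction: float | None = None,
) -> float:
    """Observed relevance score ``X = sum w(i) S_p(i)`` over shared sets.

    Sets present in only one of the two rankings are dropped and the weights
    recomputed on the intersection.
    """
    _, weights, scores = _align(ranking, relevance)
    weights = _apply_truncation(weights, top_fraction)
    return float(weights @ scores)


def optimal_and_relative(
    ranking: EARanking,
    relevance: RelevanceRanking,
    top_fraction: float | None = None,
) -> tuple[float, float]:
    """Theoretical optimum ``O_p`` and relative score ``X_bar = X / O_p``.

    ``O_p`` is the relevance score of the ranking ordered exactly by ``S_p``
    (weights derived from ``S_p`` itself, larger-is-extreme, so ties in
    ``S_p`` are handled the same tie-aware way). ``X_bar = 1`` iff the
    method's order matches the relevance order modulo ties; an all-zero
    optimum yields ``X_bar = 0`` with a warning.
    """
    _, weights, scores = _align(ranking, relevance)
    weights = _apply_truncation(weights, top_fraction)
    x = float(weights @ scores)
    w_opt = _apply_truncation(ranks_to_weights(scores, orientation="larger"), top_fraction)
    o_p = float(w_opt @ scores)
    if o_p <= 0:
        logger.warning("optimal relevance score is 0; defining relative score as 0")
        return o_p, 0.0
    return o_p, x / o_p


def random_ranking_pvalue(
    ranking: EARanking,
    relevance: RelevanceRanking,
    n_random: int = 1000,
    seed: int = 0,
) -> float:
    """Probability that a random ranking scores at least the observed ``X``.

    Random rankings place the shared sets in uniformly random order and use
    the tie-free weights ``1 - r/N``. When ``N! <= 10**4`` all orderings are
    enumerated exactly (p = proportion of orderings with score >= X);
    otherwise ``n_random`` samples give ``p = (b + 1) / (n_random + 1)``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    _, weights, scores = _align(ranking, relevance)
    x = float(weights @ scores)
    n = scores.size
    w_free = 1.0 - np.arange(1, n + 1) / n
    if math.factorial(n) <= EXHAUSTIVE_LIMIT:
        count = 0
        total = 0
        for perm in _all_permutations(range(n)):
            total += 1
            if float(w_free[list(perm)] @ scores) >= x - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_random):
        b += float(w_free[rng.permutation(n)] @ scores) >= x - 1e-12
    return (b + 1) / (n_random + 1)


def label_permutation_pvalue(
    method: str,
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    relevance: RelevanceRanking,
    n_perm: int = 100,
    seed: int = 0,
    method_params: dict | None = None,
) -> float:
    """Label-permutation null for the observed relevance score.

    Re-runs the method on ``n_perm`` datasets with shuffled group labels
    (within blocks when present), scores each resulting ranking, and returns
    the upper-tail ``(b + 1)/(B + 1)`` p-value. This null preserves ranking
    dependencies imposed by structural overlaps between gene sets, unlike the
    fully random ranking null. A permutation on which the method fails is
    dropped with a warning; more than 10% failures is an error.
    """
    from .methods import permuted_indicators, run_method  # deferred import

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    params = dict(method_params or {})
    observed = run_method(method, dataset, collection, **params)
    x_obs = relevance_score(observed, relevance)

    rng = np.random.default_rng(seed)
    ind = dataset.group_indicator()
    g1, g2 = dataset.group_levels
    perms = permuted_indicators(ind, n_perm, rng, dataset.blocks)
    null_scores: list[float] = []
    failures = 0
    for i in range(n_perm):
        labels = [g2 if v else g1 for v in perms[i]]
        try:
            shuffled = dataset.with_groups(labels)
            if "seed" in params or _method_takes_seed(method):
                params_i = {**params, "seed": int(rng.integers(2**31 - 1))}
            else:
                params_i = params
            rank_i = run_method(method, shuffled, collection, **params_i)
            null_scores.append(relevance_score(rank_i, relevance))
        except Exception as exc:  # one bad permutation should not kill the run
            failures += 1
            logger.warning("permutation %d failed for %s: %s", i, method, exc)
    if failures > 0.1 * n_perm:
        raise RuntimeError(
            f"{failures}/{n_perm} label permutations failed for method {method!r}"
        )
    b = int(np.sum(np.asarray(null_scores) >= x_obs))
    return (b + 1) / (len(null_scores) + 1)


def _method_takes_seed(method: str) -> bool:
    from .methods import get_method

    return get_method(method).needs_permutations


@dataclass
class RelevanceResult:
    """Relevance assessment of one method on one dataset."""

    method: str
    dataset: str
    hypothesis: Hypothesis
    x: float
    o_p: float
    x_bar: float
    p_random: float | None = None
    p_labelperm: float | None = None

    def __post_init__(self) -> None:
        if self.o_p > 0 and not -1e-9 <= self.x_bar <= 1 + 1e-9:
            raise ValueError(f"relative score {self.x_bar} outside [0, 1]")


def evaluate_relevance(
    ranking: EARanking,
    relevance: RelevanceRanking,
    n_random: int | None = 1000,
    seed: int = 0,
    top_fraction: float | None = None,
) -> RelevanceResult:
    """Bundle X, O_p, X_bar and (optionally) the random-ranking p-value."""
    x = relevance_score(ranking, relevance, top_fraction=top_fraction)
    o_p, x_bar = optimal_and_relative(ranking, relevance, top_fraction=top_fraction)
    p_random = (
        random_ranking_pvalue(ranking, relevance, n_random=n_random, seed=seed)
        if n_random
        else None
    )
    return RelevanceResult(
        method=ranking.method,
        dataset=ranking.dataset,
        hypothesis=ranking.hypothesis,
        x=x,
        o_p=o_p,
        x_bar=x_bar,
        p_random=p_random,
    )
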