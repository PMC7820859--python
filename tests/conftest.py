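"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gsebench import (
    EARanking,
    ExpressionDataset,
    GeneSetCollection,
    Hypothesis,
    make_scenario,
    simulate_expression,
)
from gsebench.methods import assemble_ranking


# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and independent of the implementation)
# ---------------------------------------------------------------------------

def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH by literal definition: adj_i = min over j>=i of p_(j)*n/j."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    for pos in range(n):
        candidates = [p[order[j]] * n / (j + 1) for j in range(pos, n)]
        adj[order[pos]] = min(1.0, min(candidates))
    return adj


def brute_force_es(stats_vec: np.ndarray, member: np.ndarray, exponent: float) -> float:
    """Enrichment score by explicit walk over every prefix of the ranked list."""
    order = np.argsort(-stats_vec, kind="stable")
    member = member[order]
    n = member.size
    n_hit = int(member.sum())
    if exponent == 0:
        hit_weights = np.ones(n)
        denom = n_hit
    else:
        hit_weights = np.abs(stats_vec[order]) ** exponent
        denom = hit_weights[member].sum()
        if denom == 0:
            hit_weights = np.ones(n)
            denom = n_hit
    best = 0.0
    running = 0.0
    for i in range(n):
        if member[i]:
            running += hit_weights[i] / denom
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def hypergeom_tail_by_enumeration(N: int, K: int, m: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration over all m-subsets."""
    from itertools import combinations

    universe = range(N)
    de = set(range(K))
    total = 0
    hits = 0
    for subset in combinations(universe, m):
        total += 1
        if len(de.intersection(subset)) >= k:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_dataset() -> ExpressionDataset:
    """500 genes x 16 samples, 30% DE, log-intensity; fixed seed."""
    ds, _ = simulate_expression(
        n_genes=500, n_per_group=8, de_fraction=0.3, effect_size=1.0, seed=11
    )
    return ds

@pytest.fixture(scope="session")
def small_truth():
    _, truth = simulate_expression(
        n_genes=500, n_per_group=8, de_fraction=0.3, effect_size=1.0, seed=11
    )
    return truth


@pytest.fixture(scope="session")
def null_dataset() -> ExpressionDataset:
    """400 genes x 16 samples with no differential expression."""
    ds, _ = simulate_expression(n_genes=400, n_per_group=8, de_fraction=0.0, seed=23)
    return ds


@pytest.fixture(scope="session")
def small_scenario(small_dataset, small_truth):
    collection, relevance, truth = make_scenario(
        small_dataset, small_truth, n_sets=20, set_size_range=(8, 30), seed=7
    )
    return collection, relevance, truth


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    return GeneSetCollection(
        sets={
            "S1": ["g1", "g2", "g3"],
            "S2": ["g2", "g4"],
            "S3": ["g5", "g6", "g7", "g8"],
        },
        descriptions={"S1": "first", "S2": "second", "S3": "third"},
    )


def ranking_from_pvalues(
    p_values, set_ids=None, statistics=None, method="toy", hypothesis=Hypothesis.COMPETITIVE
) -> EARanking:
    """Build a minimal EARanking straight from p-values (test helper)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    ids = list(set_ids) if set_ids is not None else [f"S{i}" for i in range(n)]
    stats_arr = (
        np.asarray(statistics, dtype=float) if statistics is not None else -p
    )
    return assemble_ranking(
        set_ids=ids,
        sizes=[10] * n,
        statistics=stats_arr,
        p_values=p,
        method=method,
        hypothesis=hypothesis,
    )
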