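"""Benchmark orchestration and the method x dataset report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GeneSetCollection, RelevanceRanking
from .methods import get_method, run_method
from .relevance import (
    RelevanceResult,
    evaluate_relevance,
    label_permutation_pvalue,
)
from .assays import significance_fraction

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkReport", "run_benchmark"]

REPORT_COLUMNS = [
    "method",
    "dataset",
    "hypothesis",
    "n_sets",
    "runtime_s",
    "frac_nominal",
    "frac_fdr",
    "x",
    "o_p",
    "x_bar",
    "p_random",
    "p_labelperm",
]


@dataclass
class BenchmarkReport:
    """Per method x dataset benchmark outcomes plus run provenance."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    relevance_results: list[RelevanceResult] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "rows": json.loads(self.table.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def run_benchmark(
    datasets: Sequence[ExpressionDataset],
    collection: GeneSetCollection,
    relevance: RelevanceRanking,
    methods: Sequence[str],
    alpha: float = 0.05,
    n_random: int = 1000,
    with_labelperm: bool = False,
    labelperm_n: int = 50,
    seed: int = 0,
    method_params: dict[str, dict] | None = None,
) -> BenchmarkReport:
    """Run every method on every dataset; collect runtime, significance
    fractions and relevance scores.

    A method failing on a dataset is recorded as an NA row and the run
    continues, mirroring how a multi-dataset compendium is processed.
    """
    method_params = method_params or {}
    rng = np.random.default_rng(seed)
    rows = []
    rel_results: list[RelevanceResult] = []
    for ds in datasets:
        for m in methods:
            spec = get_method(m)
            params = dict(method_params.get(m, {}))
            if spec.needs_permutations:
                params.setdefault("seed", int(rng.integers(2**31 - 1)))
            row = {
                "method": m,
                "dataset": ds.name,
                "hypothesis": spec.hypothesis.value,
            }
            try:
                t0 = time.perf_counter()
                ranking = run_method(m, ds, collection, **params)
                elapsed = time.perf_counter() - t0
                res = evaluate_relevance(
                    ranking,
                    relevance,
                    n_random=n_random,
                    seed=int(rng.integers(2**31 - 1)),
                )
                if with_labelperm:
                    res.p_labelperm = label_permutation_pvalue(
                        m,
                        ds,
                        collection,
                        relevance,
                        n_perm=labelperm_n,
                        seed=int(rng.integers(2**31 - 1)),
                        method_params=params,
                    )
                rel_results.append(res)
                row.update(
                    n_sets=ranking.n_sets,
                    runtime_s=elapsed,
                    frac_nominal=significance_fraction(ranking, alpha, adjusted=False),
                    frac_fdr=significance_fraction(ranking, alpha, adjusted=True),
                    x=res.x,
                    o_p=res.o_p,
                    x_bar=res.x_bar,
                    p_random=res.p_random,
                    p_labelperm=res.p_labelperm,
                )
            except Exception as exc:
                logger.warning("method %s failed on dataset %s: %s", m, ds.name, exc)
                row.update({c: np.nan for c in REPORT_COLUMNS[3:]})
                row["error"] = str(exc)
            rows.append(row)
    table = pd.DataFrame(rows)
    for col in REPORT_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    provenance = {
        "seed": seed,
        "alpha": alpha,
        "n_random": n_random,
        "methods": list(methods),
        "datasets": [ds.name for ds in datasets],
        "collection": collection.name,
        "n_sets_in_collection": len(collection),
        "method_params": method_params,
    }
    return BenchmarkReport(
        table=table[REPORT_COLUMNS + [c for c in table.columns if c not in REPORT_COLUMNS]],
        provenance=provenance,
        relevance_results=rel_results,
    )
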