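"""Core domain types for expression data, gene sets, and enrichment rankings.

The benchmark revolves around four objects:

* :class:`ExpressionDataset` — a genes x samples matrix with a binary group
  vector (case/control), an optional blocking vector (pairing or batch), and a
  tag saying what kind of values it holds (microarray log-intensities, RNA-seq
  raw counts, or TPMs).
* :class:`GeneSetCollection` — an ordered collection of named gene sets.
* :class:`RelevanceRanking` — an a-priori phenotype-relevance score ``S_p >= 0``
  per gene set, the reference a method's ranking is benchmarked against.
* :class:`EARanking` — the output of one enrichment method on one dataset:
  per-set statistic, p-value, BH-adjusted p-value, absolute rank, and
  rank-derived weight.

Gene and sample identifiers are opaque strings; matching between a dataset's
gene universe and a gene set collection is exact and case-sensitive.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataKind",
    "Hypothesis",
    "ExpressionDataset",
    "GeneSetCollection",
    "RelevanceRanking",
    "EARanking",
    "ValidationError",
]


class ValidationError(ValueError):
    """An object violates one of the domain-type invariants."""


class DataKind(str, enum.Enum):
    """What the entries of an expression matrix represent."""

    LOG_INTENSITY = "log_intensity"
    COUNTS = "counts"
    TPM = "tpm"


class Hypothesis(str, enum.Enum):
    """Null hypothesis family of a gene set test.

    Competitive tests compare differential expression of genes inside a set
    against the background of genes outside it; self-contained tests look at
    the set in isolation.
    """

    COMPETITIVE = "competitive"
    SELF_CONTAINED = "self_contained"


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with a binary sample grouping.

    Parameters
    ----------
    matrix
        Real-valued array of shape ``(n_genes, n_samples)``.
    gene_ids, sample_ids
        Unique identifiers matching the matrix dimensions.
    groups
        One label per sample; exactly two distinct values, each with at least
        two samples. The *second* distinct value in sorted order is treated as
        the case group when a direction is needed.
    blocks
        Optional label per sample encoding pairing (e.g. matched tumor/normal
        samples) or batches; permutation procedures shuffle labels within
        blocks.
    kind
        Value semantics: ``log_intensity`` (any reals), ``counts``
        (non-negative integers), or ``tpm`` (non-negative reals).
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    groups: list[str]
    kind: DataKind = DataKind.LOG_INTENSITY
    blocks: list[str] | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.kind = DataKind(self.kind)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = [str(g) for g in self.groups]
        if self.blocks is not None:
            self.blocks = [str(b) for b in self.blocks]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.matrix.ndim != 2:
            raise ValidationError("expression matrix must be 2-dimensional")
        n_genes, n_samples = self.matrix.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n_samples} matrix columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if len(self.groups) != n_samples:
            raise ValidationError("groups must have one label per sample")
        levels = sorted(set(self.groups))
        if len(levels) != 2:
            raise ValidationError(
                f"groups must take exactly two distinct values, got {levels}"
            )
        for lev in levels:
            if self.groups.count(lev) < 2:
                raise ValidationError(f"group {lev!r} has fewer than 2 samples")
        if self.blocks is not None and len(self.blocks) != n_samples:
            raise ValidationError("blocks must have one label per sample")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("expression matrix contains non-finite values")
        if self.kind is DataKind.COUNTS:
            if np.any(self.matrix < 0) or np.any(self.matrix != np.round(self.matrix)):
                raise ValidationError("counts matrix must hold non-negative integers")
        elif self.kind is DataKind.TPM:
            if np.any(self.matrix < 0):
                raise ValidationError("tpm matrix must be non-negative")

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def group_levels(self) -> tuple[str, str]:
        """The two group labels in order of first appearance.

        Gene-level contrasts are computed as first-appearing group minus
        second-appearing group.
        """
        first = self.groups[0]
        second = next(g for g in self.groups if g != first)
        return first, second

    def group_indicator(self) -> np.ndarray:
        """Binary vector: 0 for the first-appearing group, 1 for the other."""
        second = self.group_levels[1]
        return np.asarray([1 if g == second else 0 for g in self.groups], dtype=int)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def with_groups(self, groups: Sequence[str] | np.ndarray) -> "ExpressionDataset":
        """Copy of the dataset with a replacement grouping vector."""
        return ExpressionDataset(
            matrix=self.matrix,
            gene_ids=self.gene_ids,
            sample_ids=self.sample_ids,
            groups=[str(g) for g in groups],
            kind=self.kind,
            blocks=self.blocks,
            name=self.name,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Ordered, named sets of gene identifiers.

    Sets keep their file/definition order. Within a set, genes are unique and
    order-preserving; sets are non-empty.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    name: str = "collection"

    def __post_init__(self) -> None:
        for set_id, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {set_id!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {set_id!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def sizes(self) -> dict[str, int]:
        return {sid: len(genes) for sid, genes in self.sets.items()}

    def universe(self) -> set[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def intersect_universe(
        self, universe: Sequence[str] | set[str], warn: bool = True
    ) -> "GeneSetCollection":
        """Restrict every set to ``universe``; drop sets emptied by it.

        The benchmark intersects at method-run time so one collection can
        serve many datasets with different measured-gene universes.
        """
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        dropped = 0
        for sid, genes in self.sets.items():
            inter = [g for g in genes if g in uni]
            if inter:
                kept[sid] = inter
            else:
                dropped += 1
        if dropped and warn:
            logger.warning(
                "%d/%d gene sets dropped: no member genes in the dataset universe",
                dropped,
                len(self.sets),
            )
        return GeneSetCollection(
            sets=kept,
            descriptions={s: d for s, d in self.descriptions.items() if s in kept},
            name=self.name,
        )


@dataclass
class RelevanceRanking:
    """A-priori phenotype-relevance scores ``S_p`` for gene sets.

    Emulates precompiled disease-relevance rankings (e.g. literature-derived
    composite scores): non-negative, ties allowed, larger means more relevant.
    """

    scores: dict[str, float]
    phenotype: str = ""

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValidationError("relevance ranking has no entries")
        for sid, s in self.scores.items():
            s = float(s)
            if not np.isfinite(s) or s < 0:
                raise ValidationError(
                    f"relevance score for {sid!r} must be a finite non-negative real, got {s}"
                )
            self.scores[sid] = s
        if not any(s > 0 for s in self.scores.values()):
            raise ValidationError("relevance ranking must contain at least one positive score")

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, set_id: str) -> float:
        return self.scores[set_id]

    def ordered_ids(self) -> list[str]:
        """Set ids by decreasing relevance, ties broken lexicographically."""
        return sorted(self.scores, key=lambda s: (-self.scores[s], s))


class EARanking:
    """Result of one enrichment method on one dataset.

    Wraps a :class:`pandas.DataFrame` with one row per gene set and columns
    ``set_id, size, statistic, p_value, adj_p, rank, weight``. Ranks are
    assigned by ascending p-value with ties broken by descending absolute set
    statistic, then lexicographic ``set_id``, so output is deterministic.
    Weights are the tie-aware rank weights ``w = 1 - r*`` where ``r*`` is the
    fraction of sets with a p-value at least as small.
    """

    COLUMNS = ["set_id", "size", "statistic", "p_value", "adj_p", "rank", "weight"]

    def __init__(
        self,
        table: pd.DataFrame,
        method: str,
        hypothesis: Hypothesis,
        dataset: str = "",
    ) -> None:
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"EARanking table missing columns: {missing}")
        _check_unique(list(table["set_id"]), "set")
        p = table["p_value"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("p-values must lie in [0, 1]")
        w = table["weight"].to_numpy(dtype=float)
        if np.any((w < 0) | (w > 1)):
            raise ValidationError("weights must lie in [0, 1]")
        self.table = table.reset_index(drop=True)[self.COLUMNS]
        self.method = method
        self.hypothesis = Hypothesis(hypothesis)
        self.dataset = dataset

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_sets(self) -> int:
        return len(self.table)

    @property
    def set_ids(self) -> list[str]:
        return list(self.table["set_id"])

    def p_values(self) -> Mapping[str, float]:
        return dict(zip(self.table["set_id"], self.table["p_value"]))

    def subset(self, set_ids: Sequence[str]) -> "EARanking":
        """Restriction to ``set_ids`` with ranks and weights recomputed."""
        from .methods._base import assemble_ranking  # local import; avoids cycle

        keep = self.table[self.table["set_id"].isin(set(set_ids))]
        return assemble_ranking(
            set_ids=list(keep["set_id"]),
            sizes=list(keep["size"]),
            statistics=keep["statistic"].to_numpy(dtype=float),
            p_values=keep["p_value"].to_numpy(dtype=float),
            method=self.method,
            hypothesis=self.hypothesis,
            dataset=self.dataset,
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EARanking(method={self.method!r}, hypothesis={self.hypothesis.value!r}, "
            f"n_sets={self.n_sets})"
        )
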