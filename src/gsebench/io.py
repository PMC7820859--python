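"""Readers and writers for the benchmark's plain-text exchange formats.

* GMT gene set files (tab-separated: id, description, member genes...).
* Expression matrices as TSV with gene ids in the first column, one column
  per sample; group and block labels travel in a small sidecar or are passed
  separately.
* Relevance rankings as two-column TSV (set id, non-negative score).

All files are UTF-8; Unix and Windows newlines are accepted and trailing
whitespace is tolerated.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DataKind,
    ExpressionDataset,
    GeneSetCollection,
    RelevanceRanking,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "filter_by_size",
    "read_relevance_table",
    "write_relevance_table",
    "read_expression_tsv",
    "write_expression_tsv",
    "GmtParseError",
]

#: Size bounds conventionally applied to gene set collections before testing.
DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 500


class GmtParseError(ValueError):
    """A GMT or relevance file could not be parsed; message names the line."""


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must carry at least three tab-separated fields: set id,
    description, and one or more gene identifiers. File order is preserved.
    Duplicate genes within a line are removed (first occurrence kept) with a
    logged warning; a duplicate set id is an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n").rstrip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise GmtParseError(f"{path.name}:{lineno}: gene set {set_id!r} has no genes")
            if set_id in sets:
                raise GmtParseError(f"{path.name}:{lineno}: duplicate set id {set_id!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s:%d: %d duplicate gene(s) removed from set %s",
                    path.name,
                    lineno,
                    len(genes) - len(deduped),
                    set_id,
                )
            sets[set_id] = deduped
            descriptions[set_id] = desc
    if not sets:
        raise GmtParseError(f"{path.name}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions, name=path.stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT, preserving set order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for set_id, genes in collection.sets.items():
            desc = collection.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


def filter_by_size(
    collection: GeneSetCollection,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> GeneSetCollection:
    """Keep exactly the sets with ``min_size <= |set| <= max_size``.

    Order is preserved. An empty result is allowed (with a warning), since a
    collection may legitimately contain only very small or very large sets.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError(f"require 1 <= min_size <= max_size, got {min_size}, {max_size}")
    kept = {
        sid: genes
        for sid, genes in collection.sets.items()
        if min_size <= len(genes) <= max_size
    }
    if not kept:
        logger.warning(
            "size filter [%d, %d] removed all %d gene sets", min_size, max_size, len(collection)
        )
    return GeneSetCollection(
        sets=kept,
        descriptions={s: d for s, d in collection.descriptions.items() if s in kept},
        name=collection.name,
    )


def read_relevance_table(path: str | Path, phenotype: str | None = None) -> RelevanceRanking:
    """Read a two-column TSV (set id, non-negative score) into a ranking.

    A single optional header row is tolerated (detected by a non-numeric
    second field on line 1). Negative or non-numeric scores are errors naming
    the offending line.
    """
    path = Path(path)
    scores: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n").rstrip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected 2 tab-separated columns"
                )
            sid, val = fields[0].strip(), fields[1].strip()
            try:
                score = float(val)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise GmtParseError(
                    f"{path.name}:{lineno}: non-numeric relevance score {val!r}"
                ) from None
            if score < 0 or not np.isfinite(score):
                raise ValidationError(
                    f"{path.name}:{lineno}: relevance score must be non-negative, got {score}"
                )
            if sid in scores:
                raise GmtParseError(f"{path.name}:{lineno}: duplicate set id {sid!r}")
            scores[sid] = score
    if not scores:
        raise GmtParseError(f"{path.name}: no relevance scores found")
    return RelevanceRanking(scores=scores, phenotype=phenotype or path.stem)


def write_relevance_table(ranking: RelevanceRanking, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("set_id\tscore\n")
        for sid, score in ranking.scores.items():
            fh.write(f"{sid}\t{score:.10g}\n")


def read_expression_tsv(
    path: str | Path,
    groups: list[str] | None = None,
    kind: DataKind | str = DataKind.LOG_INTENSITY,
    blocks: list[str] | None = None,
    name: str | None = None,
) -> ExpressionDataset:
    """Read a genes x samples TSV matrix (gene ids in the first column).

    Group labels may be embedded as a first header-like row named ``#group``
    (written by :func:`write_expression_tsv`) or passed explicitly; explicit
    labels win.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    embedded_groups: list[str] | None = None
    embedded_blocks: list[str] | None = None
    if "#group" in df.index:
        embedded_groups = [str(v) for v in df.loc["#group"]]
        df = df.drop(index="#group")
    if "#block" in df.index:
        embedded_blocks = [str(v) for v in df.loc["#block"]]
        df = df.drop(index="#block")
    use_groups = groups if groups is not None else embedded_groups
    if use_groups is None:
        raise ValueError(f"{path.name}: no group labels embedded or supplied")
    use_blocks = blocks if blocks is not None else embedded_blocks
    return ExpressionDataset(
        matrix=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        groups=use_groups,
        blocks=use_blocks,
        kind=DataKind(kind),
        name=name or path.stem,
    )


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write matrix TSV with group (and block) labels embedded as '#group'/'#block' rows."""
    path = Path(path)
    df = dataset.to_frame()
    header_rows = [pd.DataFrame([dataset.groups], index=["#group"], columns=df.columns)]
    if dataset.blocks is not None:
        header_rows.append(
            pd.DataFrame([dataset.blocks], index=["#block"], columns=df.columns)
        )
    out = pd.concat(header_rows + [df])
    out.to_csv(path, sep="\t", index_label="gene_id")
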